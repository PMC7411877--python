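"""PCA-based multivariate statistical process control (MSPC).

A principal-component model of interictal (normal) HRV vectors is
monitored with two complementary statistics.  With x the autoscaled
feature vector, V_R the 8xR loading matrix and Sigma_R the diagonal
matrix of score standard deviations:

    Q   = x^T (I - V_R V_R^T) x          squared prediction error:
                                         distance from the PC subspace,
                                         sensitive to broken correlations
    T^2 = x^T V_R Sigma_R^-2 V_R^T x     Hotelling statistic: Mahalanobis
                                         distance inside the subspace,
                                         sensitive to shifts along
                                         modeled directions

The indices mix units (ms, ms^2, counts, a ratio), so vectors are
z-scored with the training mean and standard deviation before either
statistic is evaluated.  Control limits are empirical upper alpha-
percentiles of the statistics over normal-condition samples.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .hrv_features import HRV_FIELDS, HRVVector


class ModelNotFittedError(RuntimeError):
    pass


class ModelNotTunedError(RuntimeError):
    pass


@dataclass(frozen=True)
class MonitoringStatistics:
    """Q and Hotelling T^2 at one evaluation time."""

    t_eval: float
    Q: float
    T2: float


@dataclass(frozen=True)
class MSPCModel:
    """Fitted monitoring model: autoscaling, loadings, score scales and
    (after tuning) control limits."""

    center: np.ndarray  # (8,)
    scale: np.ndarray  # (8,)
    loadings: np.ndarray  # (8, R), orthonormal columns
    sigma: np.ndarray  # (R,) score standard deviations, non-increasing
    cl_q: float | None = None
    cl_t2: float | None = None
    alpha: float | None = None
    feature_names: tuple[str, ...] = HRV_FIELDS
    metadata: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def is_tuned(self) -> bool:
        return self.cl_q is not None and self.cl_t2 is not None

    def scale_vector(self, x: np.ndarray | HRVVector) -> np.ndarray:
        if isinstance(x, HRVVector):
            x = x.as_array()
        return (np.asarray(x, dtype=float) - self.center) / self.scale

    # ---- persistence (JSON, bit-exact round trip through float repr) ----

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),  # 8 rows of R entries
            "sigma": self.sigma.tolist(),
            "cl_Q": self.cl_q,
            "cl_T2": self.cl_t2,
            "alpha": self.alpha,
            "n_components": self.n_components,
            "feature_names": list(self.feature_names),
            "metadata": self.metadata,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "MSPCModel":
        model = cls(
            center=np.array(d["center"], dtype=float),
            scale=np.array(d["scale"], dtype=float),
            loadings=np.array(d["loadings"], dtype=float),
            sigma=np.array(d["sigma"], dtype=float),
            cl_q=d.get("cl_Q"),
            cl_t2=d.get("cl_T2"),
            alpha=d.get("alpha"),
            feature_names=tuple(d.get("feature_names", HRV_FIELDS)),
            metadata=d.get("metadata", {}),
        )
        if model.loadings.shape[1] != d["n_components"]:
            raise ValueError("inconsistent n_components in model file")
        return model

    @classmethod
    def load(cls, path: str | Path) -> "MSPCModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _as_matrix(training: Sequence[HRVVector] | np.ndarray) -> np.ndarray:
    if isinstance(training, np.ndarray):
        X = np.asarray(training, dtype=float)
    else:
        X = np.array([v.as_array() for v in training], dtype=float)
    if X.ndim != 2:
        raise ValueError("training data must be a 2-D collection of vectors")
    return X


def fit_model(
    training: Sequence[HRVVector] | np.ndarray,
    n_components: int = 6,
    metadata: dict | None = None,
) -> MSPCModel:
    """Fit the PCA monitoring model on normal-condition vectors.

    Vectors are autoscaled (z-scored per feature); the principal
    directions are the eigenvectors of the training correlation matrix,
    ordered by decreasing eigenvalue, and the score standard deviations
    are the square roots of the eigenvalues.  Loadings follow a
    deterministic sign convention (largest-magnitude element positive)
    so serialized models are reproducible.

    Control limits are left unset; see `tune_control_limits`.
    """
    X = _as_matrix(training)
    n, p = X.shape
    if not 1 <= n_components <= p:
        raise ValueError(f"n_components must be in [1, {p}]")
    if n < 10 * n_components:
        raise ValueError(
            f"need >= {10 * n_components} training vectors for "
            f"{n_components} components, got {n}"
        )
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    zero = np.flatnonzero(scale == 0.0)
    if zero.size:
        names = [HRV_FIELDS[i] if p == len(HRV_FIELDS) else str(i) for i in zero]
        raise ValueError(f"zero-variance feature(s) cannot be autoscaled: {names}")
    Z = (X - center) / scale
    corr = Z.T @ Z / n
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    V = eigvec[:, :n_components].copy()
    lam = np.clip(eigval[:n_components], 0.0, None)
    # sign convention: largest-|loading| element of each column positive
    for r in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, r]))
        if V[j, r] < 0:
            V[:, r] = -V[:, r]
    if np.any(lam <= 0.0):
        raise ValueError("retained component with non-positive variance")
    return MSPCModel(
        center=center,
        scale=scale,
        loadings=V,
        sigma=np.sqrt(lam),
        metadata=metadata or {},
    )


def q_statistic(model: MSPCModel, x: np.ndarray | HRVVector) -> float:
    """Squared prediction error of one vector (distance from the PC
    subspace after autoscaling)."""
    if model.loadings is None:
        raise ModelNotFittedError("model has no loadings")
    z = model.scale_vector(x)
    resid = z - model.loadings @ (model.loadings.T @ z)
    return float(resid @ resid)


def t2_statistic(model: MSPCModel, x: np.ndarray | HRVVector) -> float:
    """Hotelling T^2 of one vector (sum of squared unit-scaled scores)."""
    if np.any(model.sigma == 0.0):
        raise ValueError("degenerate component: sigma contains zero")
    z = model.scale_vector(x)
    scores = model.loadings.T @ z
    return float(np.sum((scores / model.sigma) ** 2))


def monitoring_statistics(
    model: MSPCModel,
    X: np.ndarray | Sequence[HRVVector],
    t_eval: np.ndarray | None = None,
) -> list[MonitoringStatistics]:
    """Vectorized Q and T^2 over a batch of vectors."""
    if not isinstance(X, np.ndarray):
        if t_eval is None:
            t_eval = np.array([v.t_eval for v in X])
        X = np.array([v.as_array() for v in X], dtype=float)
    Z = (X - model.center) / model.scale
    scores = Z @ model.loadings
    resid = Z - scores @ model.loadings.T
    q = np.einsum("ij,ij->i", resid, resid)
    t2 = np.sum((scores / model.sigma) ** 2, axis=1)
    if t_eval is None:
        t_eval = np.arange(len(q), dtype=float)
    return [MonitoringStatistics(float(t), float(qq), float(tt))
            for t, qq, tt in zip(t_eval, q, t2)]


def tune_control_limits(
    model: MSPCModel,
    normal_stats: Sequence[MonitoringStatistics],
    alpha: float = 99.0,
) -> MSPCModel:
    """Set cl_Q and cl_T2 to the empirical upper alpha-percentile of the
    statistics over normal-condition samples (linear interpolation
    between order statistics)."""
    if len(normal_stats) < 100:
        raise ValueError("control-limit tuning needs >= 100 normal samples")
    if not 0.0 < alpha < 100.0:
        raise ValueError("alpha must be a percentage in (0, 100)")
    q = np.array([s.Q for s in normal_stats], dtype=float)
    t2 = np.array([s.T2 for s in normal_stats], dtype=float)
    return dataclasses.replace(
        model,
        cl_q=float(np.percentile(q, alpha)),
        cl_t2=float(np.percentile(t2, alpha)),
        alpha=alpha,
    )
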