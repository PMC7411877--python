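"""Heart rate variability indices from a 3-minute RRI window.

Eight indices are computed per window, in a fixed order that downstream
monitoring relies on:

time domain
    meanNN  mean interval (ms)
    SDNN    standard deviation of intervals (ms, population divisor)
    RMSSD   root mean square of successive differences (ms)
    NN50    count of successive differences exceeding 50 ms

frequency domain (cubic-spline resampling of the tachogram at 4 Hz,
autoregressive PSD of order 40 fitted by the Burg method)
    TP      total spectral power over 0-0.4 Hz (ms^2)
    LF      power in 0.04-0.15 Hz (ms^2), sympathetic+parasympathetic
    HF      power in 0.15-0.4 Hz (ms^2), parasympathetic (respiratory)
    LF/HF   sympathovagal balance (dimensionless)

The AR spectrum is one-sided, so its integral over [0, rate/2] equals
the variance of the resampled series (DC removed before fitting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from statsmodels.regression.linear_model import burg as _burg
from statsmodels.regression.linear_model import yule_walker as _yule_walker

from .rri_stream import InsufficientDataError, RRIRecord, RRIWindow

#: Column order of the HRV feature vector consumed by MSPC monitoring.
HRV_FIELDS = ("meanNN", "SDNN", "RMSSD", "NN50", "TP", "LF", "HF", "LF_HF")


@dataclass(frozen=True)
class HRVConfig:
    """Tunable parameters of the feature extractor.

    All defaults follow standard short-term HRV practice: a 180-s
    window, 4-Hz resampling, AR order 40, and the canonical LF/HF band
    edges.  `tp_mode` selects whether total power is the PSD integral
    over the monitored band (``psd_band``) or the time-domain variance
    of the window (``variance``).
    """

    span: float = 180.0
    resample_rate: float = 4.0
    ar_order: int = 40
    ar_method: str = "burg"  # or "yule_walker"
    n_freq: int = 1024
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)
    tp_band: tuple[float, float] = (0.0, 0.40)
    tp_mode: str = "psd_band"
    sdnn_ddof: int = 0
    lf_hf_sentinel: float = 1e6


DEFAULT_CONFIG = HRVConfig()


@dataclass(frozen=True)
class HRVVector:
    """The 8-index feature vector at one evaluation time."""

    t_eval: float
    meanNN: float
    SDNN: float
    RMSSD: float
    NN50: int
    TP: float
    LF: float
    HF: float
    LF_HF: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in HRV_FIELDS], dtype=float)


@dataclass(frozen=True)
class ResampledSeries:
    """Uniformly resampled tachogram."""

    values: np.ndarray  # ms
    rate: float  # Hz
    t0: float  # s


@dataclass(frozen=True)
class PSDEstimate:
    """AR power spectral density on a dense frequency grid."""

    freqs: np.ndarray  # Hz
    density: np.ndarray  # ms^2 / Hz
    ar_order: int


def _as_arrays(window: RRIWindow | Sequence[RRIRecord]) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(window, RRIWindow):
        return window.times(), window.rris()
    t = np.array([r.t_beat for r in window], dtype=float)
    y = np.array([r.rri for r in window], dtype=float)
    return t, y


def time_domain_indices(
    window: RRIWindow | Sequence[RRIRecord] | Sequence[float],
    sdnn_ddof: int = 0,
) -> tuple[float, float, float, int]:
    """meanNN, SDNN, RMSSD and NN50 of the buffered intervals.

    NN50 counts strictly greater-than-50-ms successive differences.
    """
    if isinstance(window, RRIWindow):
        rris = window.rris()
    elif len(window) and isinstance(window[0], RRIRecord):
        rris = np.array([r.rri for r in window], dtype=float)
    else:
        rris = np.asarray(window, dtype=float)
    if rris.size < 2:
        raise InsufficientDataError("time-domain indices need at least 2 RRIs")
    diffs = np.diff(rris)
    mean_nn = float(rris.mean())
    sdnn = float(rris.std(ddof=sdnn_ddof))
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    nn50 = int(np.count_nonzero(np.abs(diffs) > 50.0))
    return mean_nn, sdnn, rmssd, nn50


def resample(
    window: RRIWindow | Sequence[RRIRecord],
    rate: float = 4.0,
) -> ResampledSeries:
    """Cubic-spline interpolation of the tachogram on a uniform grid.

    The spline is evaluated strictly inside the knot range (no
    extrapolation), starting at the first beat time.
    """
    t, y = _as_arrays(window)
    if t.size < 4:
        raise InsufficientDataError("cubic-spline resampling needs >= 4 beats")
    spline = CubicSpline(t, y)
    n = int(np.floor((t[-1] - t[0]) * rate)) + 1
    grid = t[0] + np.arange(n) / rate
    return ResampledSeries(values=spline(grid), rate=rate, t0=float(t[0]))


_BASIS_CACHE: dict[tuple[int, int, float], np.ndarray] = {}


def _freq_response_basis(order: int, n_freq: int, fs: float) -> np.ndarray:
    """exp(-2*pi*i*f*k/fs) on the frequency grid; data-independent, so
    cached across the per-beat monitoring cadence."""
    key = (order, n_freq, fs)
    if key not in _BASIS_CACHE:
        freqs = np.linspace(0.0, fs / 2.0, n_freq)
        k = np.arange(1, order + 1)
        _BASIS_CACHE[key] = np.exp(-2j * np.pi * np.outer(freqs, k) / fs)
    return _BASIS_CACHE[key]


def ar_psd(
    series: ResampledSeries,
    order: int = 40,
    n_freq: int = 1024,
    method: str = "burg",
) -> PSDEstimate:
    """One-sided AR power spectral density of the mean-removed series.

    The Burg method (default) estimates the AR coefficients by
    minimizing forward+backward prediction error, the standard choice
    for short HRV windows; Yule-Walker is available as a fallback.
    """
    x = np.asarray(series.values, dtype=float)
    if x.size <= order:
        raise InsufficientDataError(
            f"AR({order}) fit needs more than {order} samples, got {x.size}"
        )
    x = x - x.mean()
    fs = series.rate
    freqs = np.linspace(0.0, fs / 2.0, n_freq)
    if np.allclose(x, 0.0):
        return PSDEstimate(freqs=freqs, density=np.zeros_like(freqs), ar_order=order)
    if method == "burg":
        rho, sigma2 = _burg(x, order=order, demean=False)
    elif method == "yule_walker":
        # biased (windowed) autocorrelation: guarantees a stable AR model
        rho, sigma = _yule_walker(x, order=order, demean=False, method="mle")
        sigma2 = sigma**2
    else:
        raise ValueError(f"unknown AR method {method!r}")
    denom = np.abs(1.0 - _freq_response_basis(order, n_freq, fs) @ rho) ** 2
    # one-sided density: integrates to the series variance over [0, fs/2]
    density = 2.0 * sigma2 / fs / denom
    return PSDEstimate(freqs=freqs, density=density, ar_order=order)


def _band_integral(psd: PSDEstimate, lo: float, hi: float) -> float:
    """Trapezoid integral of the density over [lo, hi], with the band
    edges added by linear interpolation when they fall between grid
    points."""
    f, d = psd.freqs, psd.density
    inside = (f > lo) & (f < hi)
    fs = np.concatenate(([lo], f[inside], [hi]))
    ds = np.concatenate(([np.interp(lo, f, d)], d[inside], [np.interp(hi, f, d)]))
    return float(np.trapezoid(ds, fs))


def band_powers(
    psd: PSDEstimate,
    config: HRVConfig = DEFAULT_CONFIG,
) -> tuple[float, float, float, float]:
    """TP, LF, HF band powers and the LF/HF ratio.

    A zero HF power yields the configured sentinel ratio rather than an
    exception, so monitoring never halts on a degenerate window.
    """
    if psd.freqs[-1] < config.hf_band[1]:
        raise ValueError("PSD grid does not cover the HF band")
    lf = _band_integral(psd, *config.lf_band)
    hf = _band_integral(psd, *config.hf_band)
    tp = _band_integral(psd, *config.tp_band)
    lf_hf = lf / hf if hf > 0.0 else config.lf_hf_sentinel
    return tp, lf, hf, lf_hf


def extract_hrv_vector(
    window: RRIWindow | Sequence[RRIRecord],
    config: HRVConfig = DEFAULT_CONFIG,
) -> HRVVector:
    """Assemble the 8-element HRV vector for one window."""
    t, y = _as_arrays(window)
    mean_nn, sdnn, rmssd, nn50 = time_domain_indices(y, sdnn_ddof=config.sdnn_ddof)
    series = resample(window, rate=config.resample_rate)
    psd = ar_psd(series, order=config.ar_order, n_freq=config.n_freq,
                 method=config.ar_method)
    tp, lf, hf, lf_hf = band_powers(psd, config)
    if config.tp_mode == "variance":
        tp = float(y.var(ddof=config.sdnn_ddof))
    return HRVVector(
        t_eval=float(t[-1]),
        meanNN=mean_nn, SDNN=sdnn, RMSSD=rmssd, NN50=nn50,
        TP=tp, LF=lf, HF=hf, LF_HF=lf_hf,
    )


def iter_hrv_vectors(
    records: Iterable[RRIRecord],
    config: HRVConfig = DEFAULT_CONFIG,
    step_s: float = 0.0,
) -> Iterator[HRVVector]:
    """Slide the window over an accepted-beat stream, yielding one
    vector per beat once the buffer is full (per-beat cadence), or one
    vector per `step_s` seconds when a positive stride is given.

    The per-beat cadence matches the alarm algorithm, which re-evaluates
    the HRV state on every newly measured interval.
    """
    window = RRIWindow(span=config.span)
    next_t = -np.inf
    for rec in records:
        window.append(rec)
        if window.duration_s < config.span:
            continue
        if len(window) <= max(config.ar_order, 4):
            continue
        if rec.t_beat >= next_t:
            yield extract_hrv_vector(window, config)
            if step_s > 0.0:
                next_t = rec.t_beat + step_s


def hrv_matrix(vectors: Sequence[HRVVector]) -> np.ndarray:
    """Stack vectors into an (n, 8) array in the canonical field order."""
    return np.array([v.as_array() for v in vectors], dtype=float)
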