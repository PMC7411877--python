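import numpy as np
import pytest

from hrvmspc import pipeline
from hrvmspc.mspc import MSPCModel
from hrvmspc.rri_stream import RRIRecord
from hrvmspc.synthetic import GeneratorConfig

SEED = 7


def records_from_intervals(rris_ms, t0=0.0):
    """Build a beat stream from a list of interval durations."""
    t = t0
    out = []
    for rri in rris_ms:
        t += rri / 1000.0
        out.append(RRIRecord(t_beat=t, rri=float(rri)))
    return out


@pytest.fixture
def make_records():
    return records_from_intervals


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture
def random_orthonormal_model(rng):
    """An 8x6 monitoring model with random orthonormal loadings,
    identity autoscaling and decreasing score scales."""
    A = rng.normal(size=(8, 8))
    V, _ = np.linalg.qr(A)
    return MSPCModel(
        center=np.zeros(8),
        scale=np.ones(8),
        loadings=V[:, :6],
        sigma=np.linspace(2.0, 0.5, 6),
        cl_q=1.0,
        cl_t2=1.0,
        alpha=99.0,
    )


@pytest.fixture(scope="session")
def calibrated_model():
    """MSPC model fitted and CL-tuned on synthetic interictal windows
    (independent streams; shared by the calibration and end-to-end
    tests)."""
    return pipeline.calibrate_model(seed=SEED, n_train=1000, n_tune=6000)


@pytest.fixture(scope="session")
def held_out_vectors():
    """10,000 interictal HRV vectors, one per independent stream, drawn
    from the same distribution as the calibration data."""
    return pipeline.sample_interictal_vectors(
        10_000, GeneratorConfig(), seed=SEED, salt=3
    )
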