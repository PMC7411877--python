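"""End-to-end plumbing: calibration sampling, stream monitoring and
cohort evaluation.

The monitoring model is calibrated in two steps mirroring deployment:
`fit_model` learns the PCA structure from normal HRV vectors, then
`tune_control_limits` sets the alpha-percentile control limits on a
separate normal sample.  Calibration vectors are drawn one per
independently seeded stream so they are independent draws from the
interictal distribution; sliding windows within one stream share the
oscillator phases and would give a strongly dependent sample.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import mspc, predictor
from .evaluation import false_positive_rate
from .hrv_features import DEFAULT_CONFIG, HRVConfig, extract_hrv_vector, iter_hrv_vectors
from .mspc import MonitoringStatistics, MSPCModel
from .predictor import AlarmEpisode, Mode, PredictorState, Status, step
from .rri_stream import RRIRecord, accepted, process_stream
from .synthetic import GeneratorConfig, SubjectSpec, generate_interictal, generate_subject

_SEED_MOD = 2**31 - 1


def _derive_seed(seed: int, stream_index: int, salt: int = 0) -> int:
    return (seed * 1_000_003 + salt * 7919 + stream_index) % _SEED_MOD


def sample_interictal_vectors(
    n: int,
    base_config: GeneratorConfig,
    seed: int,
    hrv_config: HRVConfig = DEFAULT_CONFIG,
    salt: int = 0,
) -> np.ndarray:
    """Draw `n` independent interictal HRV vectors, one per freshly
    seeded stream (fresh phases and noise each time)."""
    duration = hrv_config.span + 15.0
    rows = []
    for i in range(n):
        cfg = dataclasses.replace(base_config, duration=duration,
                                  seed=_derive_seed(seed, i, salt),
                                  miss_rate=0.0, ectopic_rate=0.0)
        records = generate_interictal(cfg)
        vec = next(iter_hrv_vectors(records, hrv_config))
        rows.append(vec.as_array())
    return np.array(rows)


def calibrate_model(
    seed: int,
    base_config: GeneratorConfig | None = None,
    n_train: int = 1000,
    n_tune: int = 6000,
    n_components: int = 6,
    alpha: float = 99.0,
    hrv_config: HRVConfig = DEFAULT_CONFIG,
) -> MSPCModel:
    """Fit the PCA model and tune its control limits on synthetic
    interictal data (train and tune samples are disjoint)."""
    base = base_config or GeneratorConfig()
    X_train = sample_interictal_vectors(n_train, base, seed, hrv_config, salt=1)
    X_tune = sample_interictal_vectors(n_tune, base, seed, hrv_config, salt=2)
    model = mspc.fit_model(X_train, n_components=n_components)
    stats = mspc.monitoring_statistics(model, X_tune)
    return mspc.tune_control_limits(model, stats, alpha=alpha)


def exceedance_rates(model: MSPCModel, X: np.ndarray) -> tuple[float, float]:
    """Fraction (%) of vectors whose Q / T^2 exceed the control limits."""
    stats = mspc.monitoring_statistics(model, X)
    q = np.array([s.Q for s in stats])
    t2 = np.array([s.T2 for s in stats])
    return (100.0 * float(np.mean(q > model.cl_q)),
            100.0 * float(np.mean(t2 > model.cl_t2)))


@dataclass
class MonitorResult:
    """Per-beat monitoring output for one stream."""

    episodes: list[AlarmEpisode]
    stats: list[MonitoringStatistics]
    n_beats_monitored: int


def monitor_stream(
    records: Sequence[RRIRecord],
    model: MSPCModel,
    mode: Mode = Mode.Q_ONLY,
    persistence: float = predictor.DEFAULT_PERSISTENCE_S,
    hrv_config: HRVConfig = DEFAULT_CONFIG,
    clean: bool = True,
    recovery: str = "negation",
) -> MonitorResult:
    """Run the full per-beat loop on one RRI stream.

    The stream is first cleaned with the rolling outlier screen (unless
    `clean=False`), then on every accepted beat with a full window the
    HRV vector, its Q and T^2, and one state-machine step are computed.
    Episode boundaries are reported on the stream's own time axis.
    """
    from .rri_stream import RRIWindow  # local to avoid cycle at import time

    if clean:
        cleaned, _ = process_stream(records, span=hrv_config.span)
        stream = accepted(cleaned)
    else:
        stream = list(records)

    window = RRIWindow(span=hrv_config.span)
    state = PredictorState(t_now=stream[0].t_beat if stream else 0.0)
    stats_out: list[MonitoringStatistics] = []
    episodes: list[AlarmEpisode] = []
    open_t: float | None = None
    n_monitored = 0
    for rec in stream:
        window.append(rec)
        if window.duration_s < hrv_config.span:
            continue
        if len(window) <= max(hrv_config.ar_order, 4):
            continue
        vec = extract_hrv_vector(window, hrv_config)
        q = mspc.q_statistic(model, vec)
        t2 = mspc.t2_statistic(model, vec)
        stats_out.append(MonitoringStatistics(rec.t_beat, q, t2))
        prev = state.status
        state = step(state, rec.rri / 1000.0, q, t2, model, mode,
                     persistence, recovery)
        n_monitored += 1
        if prev is Status.INTERICTAL and state.status is Status.PREICTAL:
            open_t = rec.t_beat
        elif prev is Status.PREICTAL and state.status is Status.INTERICTAL:
            episodes.append(AlarmEpisode(open_t, rec.t_beat, mode))
            open_t = None
    if open_t is not None and stream and stream[-1].t_beat > open_t:
        episodes.append(AlarmEpisode(open_t, stream[-1].t_beat, mode))
    return MonitorResult(episodes=episodes, stats=stats_out,
                         n_beats_monitored=n_monitored)


@dataclass
class CohortResult:
    """Cohort-level detection and interictal summary."""

    n_anomalies: int
    n_detected: int
    fp_per_hour: float
    interictal_exceedance_pct: float  # per-beat, pooled over interictal time
    per_subject: list[dict]

    @property
    def detection_fraction(self) -> float:
        return self.n_detected / self.n_anomalies if self.n_anomalies else float("nan")


def evaluate_cohort(
    specs: Sequence[SubjectSpec],
    model: MSPCModel,
    mode: Mode = Mode.Q_ONLY,
    hrv_config: HRVConfig = DEFAULT_CONFIG,
    interictal_margin_s: float = 600.0,
) -> CohortResult:
    """Monitor every subject's stream and score detection of the
    injected anomaly windows plus interictal false alarms.

    An anomaly is detected when any alarm episode overlaps its truth
    window.  The per-beat interictal exceedance is the fraction of
    monitored interictal beats whose driving statistic exceeds its
    control limit (before the persistence filter).
    """
    n_anom = n_det = 0
    fp_onsets = 0
    inter_hours = 0.0
    exceed = total = 0
    per_subject = []
    cl = model.cl_q if mode is Mode.Q_ONLY else model.cl_t2
    for spec in specs:
        stream, timeline = generate_subject(spec, interictal_margin_s)
        result = monitor_stream(stream, model, mode=mode, hrv_config=hrv_config)
        truth = [a.window for a in spec.anomalies]
        hits = [
            any(ep.t_start < e and s < ep.t_end for ep in result.episodes)
            for s, e in truth
        ]
        n_anom += len(truth)
        n_det += sum(hits)
        inter = timeline.interictal_intervals
        inter_s = sum(e - s for s, e in inter)
        inter_hours += inter_s / 3600.0
        subj_fp = sum(any(s <= ep.t_start < e for s, e in inter)
                      for ep in result.episodes)
        fp_onsets += subj_fp
        for st in result.stats:
            if any(s <= st.t_eval < e for s, e in inter):
                total += 1
                val = st.Q if mode is Mode.Q_ONLY else st.T2
                exceed += val > cl
        per_subject.append({
            "subject_id": spec.subject_id,
            "n_anomalies": len(truth),
            "n_detected": sum(hits),
            "n_episodes": len(result.episodes),
            "fp_onsets_interictal": subj_fp,
            "interictal_s": inter_s,
        })
    return CohortResult(
        n_anomalies=n_anom,
        n_detected=n_det,
        fp_per_hour=fp_onsets / inter_hours if inter_hours else float("nan"),
        interictal_exceedance_pct=100.0 * exceed / total if total else float("nan"),
        per_subject=per_subject,
    )
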