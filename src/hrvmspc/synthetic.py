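"""Synthetic RRI streams with the statistical structure the monitor assumes.

The interictal heart rhythm is modeled as an instantaneous RR function

    RR(t) = mean_rr + lf_amp sin(2 pi lf_freq t + phi1)
                    + hf_amp sin(2 pi hf_freq t + phi2) + noise

with the two oscillations placed in the canonical LF (~0.10 Hz,
baroreflex/Mayer waves) and HF (~0.25 Hz, respiratory sinus arrhythmia)
bands.  Beats are emitted iteratively: each interval is read from RR at
the current cumulative time, a lightweight stand-in for integral pulse
frequency modulation that is adequate for testing band placement and
correlation structure, not cardiological realism.

Measurement artifacts are injected separately: a *missed beat* merges
consecutive intervals into one long interval (high outlier), an
*ectopic-like* event splits one interval into a short/long pair (low
outlier).  Preictal anomalies shift the generator parameters inside a
time window and mix the LF/HF channels, breaking the index correlation
structure the PCA model was trained on so that the Q statistic rises.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .evaluation import LabeledTimeline
from .rri_stream import BeatFlag, RRIRecord, write_rri_csv

#: Hard floor on emitted intervals (ms); keeps pathological parameter
#: combinations from producing non-positive beats.
MIN_RRI_MS = 250.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the interictal RRI generator.

    Defaults describe a resting adult: 1000-ms mean interval, 30-ms
    oscillations at 0.10 and 0.25 Hz, 20-ms white jitter.
    """

    duration: float = 600.0  # s
    mean_rr: float = 1000.0  # ms
    lf_amp: float = 30.0  # ms
    lf_freq: float = 0.10  # Hz
    hf_amp: float = 30.0  # ms
    hf_freq: float = 0.25  # Hz
    noise_sd: float = 20.0  # ms
    miss_rate: float = 0.0  # per-beat probability
    ectopic_rate: float = 0.0  # per-beat probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if min(self.lf_amp, self.hf_amp, self.noise_sd) < 0:
            raise ValueError("amplitudes must be non-negative")
        for r in (self.miss_rate, self.ectopic_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("artifact rates must lie in [0, 1)")


@dataclass(frozen=True)
class AnomalySpec:
    """A preictal anomaly window with multiplicative parameter shifts.

    `rotation` in [0, 1] mixes the LF and HF channels (0 = none,
    1 = full swap), altering the correlation structure of the HRV
    indices without necessarily moving their means.  The default effect
    is an artifact constant calibrated so that the end-to-end pipeline
    detects the injected windows with margin.
    """

    t_onset: float
    duration: float
    mean_shift: float = 0.85
    lf_shift: float = 2.5
    hf_shift: float = 0.35
    noise_shift: float = 1.8
    rotation: float = 0.6

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("anomaly duration must be positive")
        if min(self.mean_shift, self.lf_shift, self.hf_shift, self.noise_shift) <= 0:
            raise ValueError("effect shifts must be positive")
        if not 0.0 <= self.rotation <= 1.0:
            raise ValueError("rotation strength must lie in [0, 1]")

    @property
    def window(self) -> tuple[float, float]:
        return (self.t_onset, self.t_onset + self.duration)


def generate_stream(
    config: GeneratorConfig,
    anomalies: Sequence[AnomalySpec] = (),
) -> list[RRIRecord]:
    """Emit beats of the instantaneous RR model, optionally perturbed
    inside anomaly windows.  All randomness flows from `config.seed`;
    identical configs produce identical streams."""
    for spec in anomalies:
        if spec.t_onset < 0 or spec.window[1] > config.duration:
            raise ValueError(f"anomaly window {spec.window} outside the stream")
    rng = np.random.default_rng(config.seed)
    phi1, phi2 = rng.uniform(0.0, 2.0 * math.pi, size=2)
    n_max = int(config.duration / (MIN_RRI_MS / 1000.0)) + 2
    noise = rng.normal(0.0, 1.0, size=n_max)

    w1 = 2.0 * math.pi * config.lf_freq
    w2 = 2.0 * math.pi * config.hf_freq
    records: list[RRIRecord] = []
    t = 0.0
    i = 0
    while True:
        mean_rr, lf_amp, hf_amp, noise_sd = (config.mean_rr, config.lf_amp,
                                             config.hf_amp, config.noise_sd)
        for spec in anomalies:
            s, e = spec.window
            if s <= t < e:
                mean_rr *= spec.mean_shift
                lf, hf = lf_amp * spec.lf_shift, hf_amp * spec.hf_shift
                # mix the two oscillator amplitudes across bands
                lf_amp = (1.0 - spec.rotation) * lf + spec.rotation * hf
                hf_amp = (1.0 - spec.rotation) * hf + spec.rotation * lf
                noise_sd *= spec.noise_shift
                break
        rr = (mean_rr
              + lf_amp * math.sin(w1 * t + phi1)
              + hf_amp * math.sin(w2 * t + phi2)
              + noise_sd * noise[i])
        rr = max(rr, MIN_RRI_MS)
        t += rr / 1000.0
        if t > config.duration:
            break
        records.append(RRIRecord(t_beat=t, rri=rr, flag=BeatFlag.MEASURED))
        i += 1
    return records


def generate_interictal(config: GeneratorConfig) -> list[RRIRecord]:
    """A clean interictal stream (no anomalies, no artifacts)."""
    return generate_stream(config)


@dataclass(frozen=True)
class ArtifactEvent:
    kind: str  # "miss" | "ectopic"
    index: int  # index into the corrupted stream of the first affected beat
    t_beat: float  # time of the corrupted beat
    original: tuple[float, ...]  # the true interval(s) replaced


def inject_artifacts(
    records: Sequence[RRIRecord],
    miss_rate: float,
    ectopic_rate: float,
    seed: int = 0,
) -> tuple[list[RRIRecord], list[ArtifactEvent]]:
    """Corrupt a stream with missed-beat merges and ectopic-like splits.

    A miss merges the current interval with the next one (one long
    interval); an ectopic event splits the current interval into a
    short/long pair at a 30-45% fraction.  Ground truth is returned for
    recovery scoring.  Beat times are rebuilt cumulatively, so total
    elapsed time is unchanged.
    """
    rng = np.random.default_rng(seed)
    out: list[RRIRecord] = []
    truth: list[ArtifactEvent] = []
    t = records[0].t_beat - records[0].rri / 1000.0 if records else 0.0
    i = 0
    while i < len(records):
        rri = records[i].rri
        u = rng.uniform()
        if u < miss_rate and i + 1 < len(records):
            merged = rri + records[i + 1].rri
            t += merged / 1000.0
            truth.append(ArtifactEvent("miss", len(out), t,
                                       (rri, records[i + 1].rri)))
            out.append(RRIRecord(t, merged, BeatFlag.MEASURED))
            i += 2
            continue
        if u < miss_rate + ectopic_rate:
            f = rng.uniform(0.30, 0.45)
            short, long_ = f * rri, (1.0 - f) * rri
            t_short = t + short / 1000.0
            t += rri / 1000.0
            truth.append(ArtifactEvent("ectopic", len(out), t_short,
                                       (rri,)))
            out.append(RRIRecord(t_short, short, BeatFlag.MEASURED))
            out.append(RRIRecord(t, long_, BeatFlag.MEASURED))
            i += 1
            continue
        t += rri / 1000.0
        out.append(RRIRecord(t, rri, BeatFlag.MEASURED))
        i += 1
    return out, truth


def score_artifact_recovery(
    cleaned: Sequence[RRIRecord],
    truth: Sequence[ArtifactEvent],
    tol_s: float = 1e-6,
) -> float:
    """Fraction of injected artifacts the outlier screen acted on.

    A missed-beat merge counts as recovered when the cleaned stream
    holds a ``corrected`` beat at the merged interval's end time; an
    ectopic split counts when the short interval was ``removed``.
    """
    if not truth:
        return 1.0
    corrected_t = sorted(r.t_beat for r in cleaned if r.flag is BeatFlag.CORRECTED)
    removed_t = sorted(r.t_beat for r in cleaned if r.flag is BeatFlag.REMOVED)

    def _near(ts: list[float], t: float) -> bool:
        i = np.searchsorted(ts, t)
        return any(0 <= j < len(ts) and abs(ts[j] - t) <= tol_s
                   for j in (i - 1, i))

    hits = 0
    for ev in truth:
        if ev.kind == "miss":
            hits += _near(corrected_t, ev.t_beat)
        else:
            hits += _near(removed_t, ev.t_beat)
    return hits / len(truth)


def inject_preictal(
    config: GeneratorConfig,
    spec: AnomalySpec,
) -> tuple[list[RRIRecord], tuple[float, float]]:
    """A stream with one preictal anomaly window, plus the truth interval."""
    return generate_stream(config, anomalies=[spec]), spec.window


# ---------------------------------------------------------------------------
# cohort builder


@dataclass(frozen=True)
class SubjectSpec:
    """One synthetic subject: a generator config and its anomaly windows."""

    subject_id: str
    config: GeneratorConfig
    anomalies: tuple[AnomalySpec, ...] = ()


def default_cohort_specs(
    n_subjects: int = 7,
    duration: float = 7200.0,
    seed: int = 0,
    anomaly_offsets: Sequence[float] = (2400.0, 6300.0),
    anomaly_duration: float = 300.0,
) -> list[SubjectSpec]:
    """Seven-subject study layout: each subject contributes a `duration`
    stream with one preictal anomaly per offset (seizure onset at the
    anomaly end)."""
    specs = []
    for k in range(n_subjects):
        cfg = GeneratorConfig(duration=duration, seed=seed * 1009 + k,
                              miss_rate=0.005, ectopic_rate=0.005)
        anoms = tuple(AnomalySpec(t_onset=off, duration=anomaly_duration)
                      for off in anomaly_offsets)
        specs.append(SubjectSpec(subject_id=chr(ord("A") + k), config=cfg,
                                 anomalies=anoms))
    return specs


def generate_subject(
    spec: SubjectSpec,
    interictal_margin_s: float = 600.0,
) -> tuple[list[RRIRecord], LabeledTimeline]:
    """Generate one subject's corrupted stream and its labeled timeline.

    Seizure onsets sit at the end of each anomaly window; interictal
    intervals are the stretches at least `interictal_margin_s` from
    every onset.
    """
    clean = generate_stream(spec.config, anomalies=list(spec.anomalies))
    stream, _ = inject_artifacts(clean, spec.config.miss_rate,
                                 spec.config.ectopic_rate,
                                 seed=spec.config.seed + 1)
    onsets = [a.window[1] for a in spec.anomalies]
    inter: list[tuple[float, float]] = []
    edges = [0.0]
    for onset in sorted(onsets):
        edges.extend([onset - interictal_margin_s, onset + interictal_margin_s])
    edges.append(spec.config.duration)
    for lo, hi in zip(edges[::2], edges[1::2]):
        if hi - lo > 0:
            inter.append((lo, hi))
    timeline = LabeledTimeline(
        seizure_onsets=onsets,
        interictal_intervals=inter,
        interictal_margin_s=interictal_margin_s,
    )
    return stream, timeline


def generate_cohort(
    specs: Sequence[SubjectSpec],
    out_dir: str | Path,
    interictal_margin_s: float = 600.0,
) -> dict:
    """Write per-subject RRI and label files plus a manifest JSON.

    Deterministic under the configs' seeds: the same specs produce
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"subjects": [], "interictal_margin_s": interictal_margin_s}
    total_inter_s = 0.0
    for spec in specs:
        stream, timeline = generate_subject(spec, interictal_margin_s)
        rri_file = out / f"subject_{spec.subject_id}_rri.csv"
        label_file = out / f"subject_{spec.subject_id}_labels.csv"
        write_rri_csv(stream, rri_file)
        timeline.to_csv(label_file)
        inter_s = sum(e - s for s, e in timeline.interictal_intervals)
        total_inter_s += inter_s
        manifest["subjects"].append(
            {
                "subject_id": spec.subject_id,
                "rri_file": rri_file.name,
                "label_file": label_file.name,
                "seed": spec.config.seed,
                "duration_s": spec.config.duration,
                "n_beats": len(stream),
                "seizure_onsets_s": [a.window[1] for a in spec.anomalies],
                "anomaly_windows_s": [list(a.window) for a in spec.anomalies],
                "interictal_s": inter_s,
            }
        )
    manifest["total_interictal_h"] = total_inter_s / 3600.0
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
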