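"""Evaluation of seizure-warning performance and measurement agreement.

Conventions
-----------
* All intervals are half-open ``[start, end)`` in seconds.
* A seizure counts as predicted when any alarm episode overlaps the
  horizon window ``[onset - horizon, onset)`` (15 min by default); an
  episode may begin before the window as long as it reaches into it.
  Multiple alarms before one seizure count once.
* The false positive rate is the number of alarm *onsets* falling inside
  interictal intervals, divided by the total interictal duration in hours.
* Interictal intervals must lie at least 30 min away from every seizure
  onset (the margin is configurable for short recordings).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .predictor import AlarmEpisode
from .rri_stream import RRIRecord

Interval = tuple[float, float]

#: Required separation between interictal data and any seizure onset.
INTERICTAL_MARGIN_S = 1800.0

#: Prediction horizon: an alarm within this many seconds before onset is
#: a true prediction.
DEFAULT_HORIZON_S = 900.0


def _merge(intervals: Iterable[Interval]) -> list[Interval]:
    ivs = sorted((float(s), float(e)) for s, e in intervals)
    merged: list[Interval] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class LabeledTimeline:
    """Specialist labeling of one recording: seizure onsets, interictal
    intervals and exclusion windows (with reason tags)."""

    seizure_onsets: list[float] = field(default_factory=list)
    interictal_intervals: list[Interval] = field(default_factory=list)
    exclusion_intervals: list[tuple[float, float, str]] = field(default_factory=list)
    interictal_margin_s: float = INTERICTAL_MARGIN_S

    def __post_init__(self) -> None:
        self.seizure_onsets = sorted(float(t) for t in self.seizure_onsets)
        self.interictal_intervals = _merge(self.interictal_intervals)
        excl = _merge((s, e) for s, e, _ in self.exclusion_intervals)
        tags = {(float(s), float(e)): tag for s, e, tag in self.exclusion_intervals}
        self.exclusion_intervals = [(s, e, tags.get((s, e), "excluded"))
                                    for s, e in excl]
        for s, e in self.interictal_intervals:
            for onset in self.seizure_onsets:
                if s - self.interictal_margin_s < onset < e + self.interictal_margin_s:
                    raise ValueError(
                        f"interictal interval ({s}, {e}) is within "
                        f"{self.interictal_margin_s} s of onset {onset}"
                    )

    # -- delimited-text round trip (kind, start_s, end_s, tag) --

    @classmethod
    def from_csv(cls, path: str | Path,
                 interictal_margin_s: float = INTERICTAL_MARGIN_S) -> "LabeledTimeline":
        df = pd.read_csv(path)
        onsets, inter, excl = [], [], []
        for _, row in df.iterrows():
            kind = str(row["kind"])
            if kind == "onset":
                onsets.append(float(row["start_s"]))
            elif kind == "interictal":
                inter.append((float(row["start_s"]), float(row["end_s"])))
            elif kind == "exclusion":
                tag = row.get("tag", "excluded")
                excl.append((float(row["start_s"]), float(row["end_s"]),
                             str(tag) if pd.notna(tag) else "excluded"))
            else:
                raise ValueError(f"unknown label kind {kind!r}")
        return cls(onsets, inter, excl, interictal_margin_s=interictal_margin_s)

    def to_csv(self, path: str | Path) -> None:
        rows = [("onset", t, t, "") for t in self.seizure_onsets]
        rows += [("interictal", s, e, "") for s, e in self.interictal_intervals]
        rows += [("exclusion", s, e, tag) for s, e, tag in self.exclusion_intervals]
        pd.DataFrame(rows, columns=["kind", "start_s", "end_s", "tag"]).to_csv(
            path, index=False)


def _overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def apply_exclusions(
    data: Sequence[AlarmEpisode] | Sequence[RRIRecord] | Sequence[Interval],
    timeline: LabeledTimeline,
):
    """Drop or clip data intersecting the timeline's exclusion windows.

    Alarm episodes and plain intervals are clipped at exclusion edges
    (and dropped when fully covered); beat records inside an exclusion
    window are dropped.
    """
    excl = [(s, e) for s, e, _ in timeline.exclusion_intervals]
    if not excl:
        return list(data)
    out = []
    for item in data:
        if isinstance(item, RRIRecord):
            if not any(s <= item.t_beat < e for s, e in excl):
                out.append(item)
            continue
        if isinstance(item, AlarmEpisode):
            span, rebuild = (item.t_start, item.t_end), \
                lambda s, e: AlarmEpisode(s, e, item.statistic)
        else:
            span, rebuild = (float(item[0]), float(item[1])), lambda s, e: (s, e)
        pieces = [span]
        for es, ee in excl:
            next_pieces = []
            for ps, pe in pieces:
                if not _overlaps((ps, pe), (es, ee)):
                    next_pieces.append((ps, pe))
                    continue
                if ps < es:
                    next_pieces.append((ps, es))
                if ee < pe:
                    next_pieces.append((ee, pe))
            pieces = next_pieces
        out.extend(rebuild(s, e) for s, e in pieces if e > s)
    return out


def sensitivity_at_horizon(
    episodes: Sequence[AlarmEpisode] | Sequence[Interval],
    onsets: Sequence[float],
    horizon: float = DEFAULT_HORIZON_S,
) -> tuple[float, list[bool]]:
    """Fraction of seizures preceded by an alarm within the horizon.

    A seizure is predicted iff some episode overlaps
    ``[onset - horizon, onset)``.
    """
    if len(onsets) == 0:
        raise ValueError("sensitivity is undefined for an empty onset list")
    spans = [(e.t_start, e.t_end) if isinstance(e, AlarmEpisode)
             else (float(e[0]), float(e[1])) for e in episodes]
    hits = [any(_overlaps(span, (onset - horizon, onset)) for span in spans)
            for onset in sorted(onsets)]
    return sum(hits) / len(hits), hits


def false_positive_rate(
    episodes: Sequence[AlarmEpisode] | Sequence[Interval],
    interictal_intervals: Sequence[Interval],
) -> float:
    """Alarm onsets inside interictal intervals, per interictal hour."""
    merged = _merge(interictal_intervals)
    hours = sum(e - s for s, e in merged) / 3600.0
    if hours <= 0:
        raise ValueError("total interictal duration must be positive")
    onsets = [e.t_start if isinstance(e, AlarmEpisode) else float(e[0])
              for e in episodes]
    n_fp = sum(any(s <= t < e for s, e in merged) for t in onsets)
    return n_fp / hours


def sign_test_one_sided(
    successes: int,
    n: int,
    chance: float = 0.5,
    direction: str = "greater",
) -> float:
    """Exact binomial tail probability of the observed success count.

    ``greater``: P(X >= successes); ``less``: P(X <= successes), with
    X ~ Binomial(n, chance).
    """
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    if direction == "greater":
        return float(sps.binom.sf(successes - 1, n, chance))
    if direction == "less":
        return float(sps.binom.cdf(successes, n, chance))
    raise ValueError(f"unknown direction {direction!r}")


def compare_fp_rates(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = False,
) -> float:
    """Two-sample t-test p-value for a difference in false positive
    rates (Welch by default).  Two identical zero-variance groups give
    p = 1 by convention."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need >= 2 values")
    if a.std() == 0.0 and b.std() == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(sps.ttest_ind(a, b, equal_var=equal_var).pvalue)


@dataclass(frozen=True)
class BlandAltman:
    """Agreement between paired measurements: mean difference (bias) and
    the bias +/- 1.96 SD limits of agreement."""

    bias: float
    loa: tuple[float, float]
    sd_diff: float
    n: int


def bland_altman(
    reference: Sequence[float],
    device: Sequence[float],
) -> BlandAltman:
    """Bland-Altman statistics of (reference - device) differences."""
    ref = np.asarray(reference, dtype=float)
    dev = np.asarray(device, dtype=float)
    if ref.shape != dev.shape:
        raise ValueError("paired sequences must have equal length")
    if ref.size < 2:
        raise ValueError("agreement analysis needs >= 2 pairs")
    d = ref - dev
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, loa=(bias - 1.96 * sd, bias + 1.96 * sd),
                       sd_diff=sd, n=ref.size)


def failure_rate_summary(
    per_subject: Sequence[tuple[int, int]],
) -> tuple[list[float], float, float]:
    """Per-subject failure percentages and their cohort mean +/- SD.

    Rates are rounded to one decimal (the precision they are reported
    at); the mean is rounded to two decimals and the SD uses the
    population divisor, matching the summary convention for small
    cohorts reported as mean +/- SD.
    """
    rates = []
    for total, outliers in per_subject:
        if total <= 0:
            raise ValueError("total RRI count must be positive")
        rates.append(round(100.0 * outliers / total, 1))
    arr = np.array(rates)
    return rates, float(round(arr.mean(), 2)), float(round(arr.std(ddof=0), 2))
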