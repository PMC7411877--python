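"""Streaming R-R interval (RRI) buffering and artifact correction.

Beat-to-beat intervals from a wearable single-lead ECG telemeter are
contaminated by missed beats (one long interval spanning several true
beats) and spurious detections (one interval split into implausibly
short pieces).  This module keeps a 180-s first-in first-out buffer of
accepted intervals and screens every incoming interval against robust
bounds derived from the buffer:

    sigma = 1.4826 * MAD(buffer)
    normal iff  median - 4*sigma < rri < median + 4*sigma

Intervals below the lower bound are removed.  Intervals above the upper
bound are interpreted as N >= 2 merged beats with N = round(rri/median)
and replaced by N equal intervals of rri/N, so total elapsed time is
conserved exactly.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Consistency factor relating the median absolute deviation to the
#: standard deviation of a Gaussian.
MAD_SCALE = 1.4826

#: Number of robust standard deviations defining the normal RRI range.
N_SIGMA = 4.0


class BeatFlag(str, Enum):
    """Provenance of an interval in a cleaned stream."""

    MEASURED = "measured"
    CORRECTED = "corrected"
    REMOVED = "removed"


class Classification(str, Enum):
    NORMAL = "normal"
    LOW_OUTLIER = "low_outlier"
    HIGH_OUTLIER = "high_outlier"


class InsufficientDataError(ValueError):
    """Raised when an operation needs more beats than the window holds."""


@dataclass(frozen=True)
class RRIRecord:
    """One beat-to-beat interval.

    Parameters
    ----------
    t_beat : float
        Elapsed time of the beat since stream start, in seconds.
    rri : float
        Interval duration in milliseconds; must be positive.
    flag : BeatFlag
        Whether the interval was measured as-is, synthesized by
        missed-beat correction, or rejected.
    """

    t_beat: float
    rri: float
    flag: BeatFlag = BeatFlag.MEASURED

    def __post_init__(self) -> None:
        if self.rri <= 0:
            raise ValueError(f"rri must be positive, got {self.rri}")


@dataclass(frozen=True)
class OutlierStats:
    """Robust location/scale of the current buffer and the normal range."""

    median_rri: float
    mad: float
    sigma: float
    lower: float
    upper: float


class RRIWindow:
    """FIFO buffer holding the most recent ~`span` seconds of accepted RRIs.

    Eviction keeps the buffer covering at least `span` seconds whenever
    enough data has been seen: the oldest record is dropped only while
    the remaining records still sum to `span` or more.
    """

    def __init__(self, span: float = 180.0):
        if span <= 0:
            raise ValueError("span must be positive")
        self.span = span
        self._records: deque[RRIRecord] = deque()
        self._sum_ms: float = 0.0

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    @property
    def records(self) -> tuple[RRIRecord, ...]:
        return tuple(self._records)

    @property
    def duration_s(self) -> float:
        """Seconds of heartbeat time currently covered by the buffer."""
        return self._sum_ms / 1000.0

    def rris(self) -> np.ndarray:
        return np.fromiter((r.rri for r in self._records), dtype=float,
                           count=len(self._records))

    def times(self) -> np.ndarray:
        return np.fromiter((r.t_beat for r in self._records), dtype=float,
                           count=len(self._records))

    def append(self, record: RRIRecord) -> None:
        if record.flag is BeatFlag.REMOVED:
            raise ValueError("removed records never enter the HRV buffer")
        if self._records and record.t_beat <= self._records[-1].t_beat:
            raise ValueError("t_beat must be strictly increasing")
        self._records.append(record)
        self._sum_ms += record.rri
        span_ms = self.span * 1000.0
        while self._records and self._sum_ms - self._records[0].rri >= span_ms:
            self._sum_ms -= self._records.popleft().rri


def compute_outlier_stats(window: RRIWindow | Sequence[float]) -> OutlierStats:
    """Median/MAD statistics and the ±4-sigma normal range of a buffer.

    Raises
    ------
    InsufficientDataError
        If the buffer holds fewer than two intervals.
    """
    rris = window.rris() if isinstance(window, RRIWindow) else np.asarray(window, float)
    if rris.size < 2:
        raise InsufficientDataError("outlier statistics need at least 2 RRIs")
    med = float(np.median(rris))
    mad = float(np.median(np.abs(rris - med)))
    sigma = MAD_SCALE * mad
    return OutlierStats(
        median_rri=med,
        mad=mad,
        sigma=sigma,
        lower=med - N_SIGMA * sigma,
        upper=med + N_SIGMA * sigma,
    )


#: Relative half-width of the acceptance band used when the buffer is
#: constant (MAD = 0) and the ±4-sigma range collapses to a point.
DEGENERATE_REL_TOL = 0.20


def classify_rri(stats: OutlierStats, rri: float) -> Classification:
    """Classify one interval against the buffer's normal range.

    The normal range is an open interval: an interval exactly on a bound
    is assigned to the adjacent outlier class.  When the buffer is
    constant (sigma = 0) the band degenerates; intervals within ±20% of
    the median are then accepted and anything else is classified by sign.
    """
    if stats.sigma == 0.0:
        if abs(rri - stats.median_rri) <= DEGENERATE_REL_TOL * stats.median_rri:
            return Classification.NORMAL
        return (Classification.LOW_OUTLIER if rri < stats.median_rri
                else Classification.HIGH_OUTLIER)
    if rri <= stats.lower:
        return Classification.LOW_OUTLIER
    if rri >= stats.upper:
        return Classification.HIGH_OUTLIER
    return Classification.NORMAL


def correct_high_outlier(rri: float, median_rri: float) -> list[float]:
    """Split a too-long interval into the estimated number of missed beats.

    N = round(rri / median) equal intervals of rri/N are returned; their
    sum equals the input exactly.  If N rounds to 1 (or less) the
    interval is returned unchanged as a single corrected beat.
    """
    if median_rri <= 0:
        raise ValueError("median_rri must be positive")
    n = int(math.floor(rri / median_rri + 0.5))
    if n <= 1:
        return [rri]
    return [rri / n] * n


@dataclass
class FailureReport:
    """Outlier bookkeeping for a processed stream."""

    total: int = 0
    outliers: int = 0

    @property
    def failure_rate_pct(self) -> float:
        return 0.0 if self.total == 0 else 100.0 * self.outliers / self.total

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "outliers": self.outliers,
            "failure_rate_pct": self.failure_rate_pct,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def process_stream(
    records: Iterable[RRIRecord],
    span: float = 180.0,
    warmup_s: float = 30.0,
) -> tuple[list[RRIRecord], FailureReport]:
    """Clean a time-ordered RRI stream with the rolling-buffer screen.

    Each incoming interval is tested against statistics computed from
    the buffer *excluding* the candidate.  Screening starts once the
    buffer covers at least `warmup_s` seconds; earlier beats pass
    through flagged ``measured``.

    Removed beats stay in the output (flag ``removed``) with their
    original timestamps but never enter the buffer, so later medians are
    computed from accepted data only.  Corrected replacements subdivide
    the original interval, conserving cumulative time exactly.

    Returns
    -------
    (cleaned, report)
        `cleaned` is the full flagged record sequence; `report` counts
        input beats and detected outliers.
    """
    window = RRIWindow(span=span)
    out: list[RRIRecord] = []
    report = FailureReport()

    for rec in records:
        report.total += 1
        screening = len(window) >= 2 and window.duration_s >= warmup_s
        if not screening:
            accepted = RRIRecord(rec.t_beat, rec.rri, BeatFlag.MEASURED)
            window.append(accepted)
            out.append(accepted)
            continue

        stats = compute_outlier_stats(window)
        cls = classify_rri(stats, rec.rri)
        if cls is Classification.NORMAL:
            accepted = RRIRecord(rec.t_beat, rec.rri, BeatFlag.MEASURED)
            window.append(accepted)
            out.append(accepted)
        elif cls is Classification.LOW_OUTLIER:
            report.outliers += 1
            out.append(RRIRecord(rec.t_beat, rec.rri, BeatFlag.REMOVED))
        else:
            report.outliers += 1
            parts = correct_high_outlier(rec.rri, stats.median_rri)
            # replacements subdivide [t_end - rri, t_end] on the original timeline
            t_start = rec.t_beat - rec.rri / 1000.0
            t = t_start
            for part in parts:
                t += part / 1000.0
                corrected = RRIRecord(t, part, BeatFlag.CORRECTED)
                window.append(corrected)
                out.append(corrected)
    return out, report


def accepted(records: Iterable[RRIRecord]) -> list[RRIRecord]:
    """The sub-stream that feeds HRV analysis (drop removed beats)."""
    return [r for r in records if r.flag is not BeatFlag.REMOVED]


# ---------------------------------------------------------------------------
# delimited-text I/O (columns: t_beat_s, rri_ms[, flag])

def read_rri_csv(path: str | Path, sep: str = ",") -> list[RRIRecord]:
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if not {"t_beat_s", "rri_ms"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns t_beat_s, rri_ms")
    flags = (df["flag"] if "flag" in df.columns
             else pd.Series([BeatFlag.MEASURED.value] * len(df)))
    return [
        RRIRecord(float(t), float(r), BeatFlag(f))
        for t, r, f in zip(df["t_beat_s"], df["rri_ms"], flags)
    ]


def write_rri_csv(records: Sequence[RRIRecord], path: str | Path,
                  sep: str = ",") -> None:
    df = pd.DataFrame(
        {
            "t_beat_s": [r.t_beat for r in records],
            "rri_ms": [r.rri for r in records],
            "flag": [r.flag.value for r in records],
        }
    )
    # %.17g round-trips doubles exactly through text
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
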