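"""Per-beat alarm state machine for seizure warning.

The monitored subject is in one of two states: interictal (normal) or
preictal (warning).  On every beat the monitoring statistic is compared
with its control limit.  A time counter tau accumulates the beat
intervals while the condition for *leaving* the current state holds
(exceedance while interictal, recovery while preictal) and resets to
zero otherwise; when tau reaches the persistence threshold (10 s by
default) the state toggles and tau resets.  The persistence rule
debounces transient HRV changes such as those caused by sudden motion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .mspc import ModelNotTunedError, MSPCModel

#: Seconds a statistic must remain beyond (or back within) its control
#: limit before the state toggles.
DEFAULT_PERSISTENCE_S = 10.0


class Status(str, Enum):
    INTERICTAL = "interictal"
    PREICTAL = "preictal"


class Mode(str, Enum):
    """Which monitoring statistic drives the alarm."""

    Q_ONLY = "q"
    T2_ONLY = "t2"
    EITHER = "either"


@dataclass(frozen=True)
class PredictorState:
    """State after processing one beat."""

    tau: float = 0.0
    status: Status = Status.INTERICTAL
    t_now: float = 0.0


@dataclass(frozen=True)
class AlarmEpisode:
    """One contiguous preictal interval in the state trace."""

    t_start: float
    t_end: float
    statistic: Mode

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("episode must have t_start < t_end")


def _exceeds(q: float, t2: float, model: MSPCModel, mode: Mode) -> bool:
    # equality with a control limit is not an exceedance
    if mode is Mode.Q_ONLY:
        return q > model.cl_q
    if mode is Mode.T2_ONLY:
        return t2 > model.cl_t2
    return q > model.cl_q or t2 > model.cl_t2


def _recovers(q: float, t2: float, model: MSPCModel, mode: Mode,
              recovery: str) -> bool:
    if recovery == "negation" or mode is not Mode.EITHER:
        return not _exceeds(q, t2, model, mode)
    if recovery == "literal":
        # disjunctive reading: one statistic back under its limit suffices
        return q <= model.cl_q or t2 <= model.cl_t2
    raise ValueError(f"unknown recovery rule {recovery!r}")


def step(
    state: PredictorState,
    y: float,
    q: float,
    t2: float,
    model: MSPCModel,
    mode: Mode = Mode.Q_ONLY,
    persistence: float = DEFAULT_PERSISTENCE_S,
    recovery: str = "negation",
) -> PredictorState:
    """Advance the state machine by one beat of duration `y` seconds.

    The default recovery rule is the logical negation of the exceedance
    condition, so the machine is a symmetric two-state debouncer; the
    ``literal`` rule (meaningful only under `Mode.EITHER`) lets a single
    statistic returning below its limit start the recovery count.
    """
    if not model.is_tuned:
        raise ModelNotTunedError("control limits must be tuned before prediction")
    if y <= 0:
        raise ValueError("beat duration must be positive seconds")
    t_now = state.t_now + y
    if state.status is Status.INTERICTAL:
        leaving = _exceeds(q, t2, model, mode)
    else:
        leaving = _recovers(q, t2, model, mode, recovery)
    tau = state.tau + y if leaving else 0.0
    status = state.status
    if tau >= persistence:
        status = (Status.PREICTAL if status is Status.INTERICTAL
                  else Status.INTERICTAL)
        tau = 0.0
    return PredictorState(tau=tau, status=status, t_now=t_now)


def run(
    stream: Iterable[tuple[float, float, float]],
    model: MSPCModel,
    mode: Mode = Mode.Q_ONLY,
    persistence: float = DEFAULT_PERSISTENCE_S,
    recovery: str = "negation",
    initial: PredictorState | None = None,
    t0: float = 0.0,
) -> tuple[list[PredictorState], list[AlarmEpisode]]:
    """Fold `step` over a stream of (rri_seconds, Q, T2) triples.

    An episode opens at each interictal-to-preictal toggle and closes at
    the next reverse toggle, or at stream end if still preictal.

    Passing the final state of one call as `initial` (with `t0` set to
    its `t_now`) continues the trace exactly as if the stream had been
    processed in one pass.
    """
    state = initial if initial is not None else PredictorState(t_now=t0)
    trace: list[PredictorState] = []
    episodes: list[AlarmEpisode] = []
    open_t: float | None = None
    if state.status is Status.PREICTAL:
        open_t = state.t_now
    for y, q, t2 in stream:
        prev = state.status
        state = step(state, y, q, t2, model, mode, persistence, recovery)
        trace.append(state)
        if prev is Status.INTERICTAL and state.status is Status.PREICTAL:
            open_t = state.t_now
        elif prev is Status.PREICTAL and state.status is Status.INTERICTAL:
            episodes.append(AlarmEpisode(open_t, state.t_now, mode))
            open_t = None
    if open_t is not None and state.t_now > open_t:
        episodes.append(AlarmEpisode(open_t, state.t_now, mode))
    return trace, episodes


def episodes_to_intervals(episodes: Sequence[AlarmEpisode]) -> list[tuple[float, float]]:
    return [(e.t_start, e.t_end) for e in episodes]
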