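"""Published worked-example inputs for the evaluation module.

These constants transcribe the printed evaluation tables of the
clinical feasibility study this method originates from, and serve as
inputs to the evaluation worked examples:

* per-seizure alarm intervals (seconds relative to seizure onset, which
  is at 0; negative times precede the onset) for the Q and Hotelling T^2
  statistics, for the fourteen analyzed seizures of seven subjects;
* per-subject beat counts and detected outlier counts from the
  measurement-reliability assessment;
* per-subject false-positive rates (alarms per interictal hour) for the
  patient and healthy-control groups.
"""

from __future__ import annotations


def _mmss(m: int, s: int) -> float:
    """minutes:seconds before onset -> negative seconds."""
    return -(60.0 * m + s)


#: Alarm intervals of the Q statistic, keyed by seizure id.  An empty
#: list means the statistic never exceeded its control limit for the
#: required persistence before that seizure.
Q_ALARM_INTERVALS: dict[str, list[tuple[float, float]]] = {
    "A1": [(_mmss(5, 10), _mmss(4, 58))],
    "A2": [(_mmss(5, 16), _mmss(2, 19))],
    "A3": [],
    "B1": [(_mmss(7, 6), _mmss(5, 16))],
    "C1": [(_mmss(14, 40), _mmss(14, 25)), (_mmss(12, 41), _mmss(11, 40))],
    "C2": [],
    "D1": [(_mmss(13, 5), _mmss(11, 15))],
    "E1": [(_mmss(16, 9), _mmss(14, 44)), (_mmss(9, 36), _mmss(6, 39))],
    "E2": [(_mmss(14, 43), _mmss(10, 36))],
    "F1": [(_mmss(12, 43), _mmss(12, 6))],
    "F2": [(_mmss(15, 41), _mmss(12, 42)), (_mmss(10, 13), _mmss(8, 44))],
    "G1": [(_mmss(14, 23), _mmss(13, 39)), (_mmss(8, 37), _mmss(4, 54)),
           (_mmss(3, 38), _mmss(1, 5))],
    "G2": [(_mmss(3, 52), _mmss(2, 59))],
    "G3": [(_mmss(12, 18), _mmss(9, 33))],
}

#: Alarm intervals of the Hotelling T^2 statistic, same layout.
T2_ALARM_INTERVALS: dict[str, list[tuple[float, float]]] = {
    "A1": [], "A2": [], "A3": [],
    "B1": [],
    "C1": [],
    "C2": [(_mmss(9, 56), _mmss(8, 16))],
    "D1": [],
    "E1": [], "E2": [],
    "F1": [(_mmss(13, 18), _mmss(10, 28)), (_mmss(6, 34), _mmss(2, 52))],
    "F2": [],
    "G1": [], "G2": [], "G3": [],
}

#: (total RRIs, detected outliers) per subject from the
#: measurement-reliability assessment.
FAILURE_COUNTS: dict[str, tuple[int, int]] = {
    "A": (245_920, 11_564),
    "B": (163_520, 577),
    "C": (159_240, 5_805),
    "D": (474_630, 31_665),
    "E": (343_770, 14_668),
    "F": (144_530, 2_446),
    "G": (419_440, 11_866),
}

#: False-positive rates (alarms per interictal hour), per subject.
FP_RATES_PATIENTS_Q = [3.34, 0.29, 1.62, 0.43, 0.67, 0.73, 0.74]
FP_RATES_PATIENTS_T2 = [1.11, 1.16, 1.62, 1.71, 0.34, 4.76, 0.37]
FP_RATES_CONTROLS_Q = [0.0, 0.0, 0.69, 0.14, 1.32, 1.30, 0.97]
FP_RATES_CONTROLS_T2 = [2.14, 1.46, 1.92, 0.56, 0.59, 0.65, 1.82]
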