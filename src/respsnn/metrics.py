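"""Breath segmentation and respiratory summary statistics.

A run is characterized breath by breath: tidal volume (Vt), period and
respiratory rate (RR), minute ventilation (Vt x RR), and the coefficient of
variation of RR over the trailing 10 breaths — "constant" breathing is
defined as CV below 4%.  Breaths are segmented at volume minima found with
a hysteresis detector so that small additive noise does not split cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BreathRecord",
    "segment_breaths",
    "cv_rr",
    "stabilization_cycle",
    "normalized_rr",
    "records_to_frame",
    "CV_THRESHOLD_PCT",
]

#: CV-of-RR threshold (percent) defining "constant" breathing.
CV_THRESHOLD_PCT = 4.0

#: Trailing window (breaths) for CV of RR.
CV_WINDOW = 10


@dataclass(frozen=True)
class BreathRecord:
    """One breathing cycle.  ``cv_rr_10`` is None until 10 breaths precede."""

    index: int
    t_start: float          # s
    period: float           # s
    rr: float               # breaths/min (= 60/period)
    vt: float               # mL (max - min within the breath)
    minute_ventilation: float  # mL/min (= vt * rr)
    cv_rr_10: float | None = None


def _minima_with_hysteresis(v: np.ndarray, band: float) -> list[int]:
    """Indices of cycle minima: a minimum is committed once the signal has
    risen ``band`` above it, and the following maximum once it has fallen
    ``band`` below."""
    minima: list[int] = []
    i_min = 0
    i_max = 0
    state = "falling"
    for i in range(1, len(v)):
        if state == "falling":
            if v[i] < v[i_min]:
                i_min = i
            elif v[i] > v[i_min] + band:
                minima.append(i_min)
                i_max = i
                state = "rising"
        else:
            if v[i] > v[i_max]:
                i_max = i
            elif v[i] < v[i_max] - band:
                i_min = i
                state = "falling"
    return minima


def segment_breaths(volume: np.ndarray, dt: float,
                    hysteresis_frac: float = 0.2) -> list[BreathRecord]:
    """Segment a volume trace (mL, sampled every ``dt`` s) into breaths.

    Boundaries are volume minima detected with a hysteresis band of
    ``hysteresis_frac`` times the overall amplitude; each breath spans two
    consecutive minima and Vt is the in-breath max minus min.  A flat trace
    yields an empty list.
    """
    v = np.asarray(volume, dtype=float)
    if len(v) < 3:
        return []
    amp = float(np.percentile(v, 97.5) - np.percentile(v, 2.5))
    if amp <= 0 or not np.isfinite(amp):
        return []
    minima = _minima_with_hysteresis(v, hysteresis_frac * amp)
    records: list[BreathRecord] = []
    for k, (a, b) in enumerate(zip(minima[:-1], minima[1:])):
        seg = v[a:b + 1]
        period = (b - a) * dt
        rr = 60.0 / period
        vt = float(seg.max() - seg.min())
        records.append(BreathRecord(
            index=k, t_start=a * dt, period=period, rr=rr, vt=vt,
            minute_ventilation=vt * rr,
        ))
    # trailing-window CV annotations
    out: list[BreathRecord] = []
    rrs = np.array([r.rr for r in records])
    for k, r in enumerate(records):
        cv = None
        if k + 1 >= CV_WINDOW:
            cv = _cv_pct(rrs[k + 1 - CV_WINDOW:k + 1])
        out.append(BreathRecord(**{**r.__dict__, "cv_rr_10": cv}))
    return out


def _cv_pct(x: np.ndarray) -> float:
    # population (n) convention, pinned
    return float(100.0 * np.std(x) / np.mean(x))


def cv_rr(records: list[BreathRecord], window: int = CV_WINDOW) -> float:
    """CV (%) of RR over the trailing ``window`` breaths (population std)."""
    if len(records) < window:
        raise ValueError(f"need at least {window} breaths, have {len(records)}")
    rrs = np.array([r.rr for r in records[-window:]])
    return _cv_pct(rrs)


def stabilization_cycle(records: list[BreathRecord],
                        threshold: float = CV_THRESHOLD_PCT,
                        window: int = CV_WINDOW) -> int | None:
    """First breath index whose trailing CV is below ``threshold`` and stays
    below it for the rest of the run; None if the run never stabilizes.

    Indices count from the start of the record list (the perturbation
    cycle), so the earliest possible answer is ``window`` - the first
    breath with a defined CV.
    """
    if len(records) < window:
        raise ValueError(f"need at least {window} breaths, have {len(records)}")
    cvs = np.array([
        _cv_pct(np.array([r.rr for r in records[k + 1 - window:k + 1]]))
        for k in range(window - 1, len(records))
    ])
    below = cvs < threshold
    # last index where CV is >= threshold; stabilization is just after it
    above = np.nonzero(~below)[0]
    if below.all():
        return window
    if len(above) and above[-1] == len(below) - 1:
        return None
    return int(above[-1] + 1 + window)


def normalized_rr(injured: list[BreathRecord], reference: list[BreathRecord],
                  window: int = CV_WINDOW) -> float:
    """Ratio of mean RR over the last ``window`` breaths, injured / reference."""
    for name, recs in (("injured", injured), ("reference", reference)):
        if len(recs) < window:
            raise ValueError(f"{name} run has {len(recs)} < {window} breaths")
    num = np.mean([r.rr for r in injured[-window:]])
    den = np.mean([r.rr for r in reference[-window:]])
    return float(num / den)


def records_to_frame(records: list[BreathRecord]) -> pd.DataFrame:
    """Per-breath records as a tidy DataFrame (one row per breath)."""
    return pd.DataFrame([r.__dict__ for r in records])
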