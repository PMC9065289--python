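"""Absorbance progress curves and initial-rate extraction.

Cosubstrate oxidation is followed spectrophotometrically (BNAH at 355 nm,
NAD(P)H at 340 nm with ε = 6220 M⁻¹cm⁻¹).  Beer-Lambert converts absorbance
to concentration, with an explicit per-well pathlength so that plate-reader
pathlength correction is a measured (or nominal) input.  The initial rate is
the ordinary-least-squares slope over the longest prefix of the trace in
which no more than a set fraction of the substrate has been consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

__all__ = ["ProgressCurve", "InitialRate", "absorbance_to_concentration", "extract_initial_rate"]

ACCEPTED = "accepted"
REJECTED = "rejected"


@dataclass(frozen=True)
class ProgressCurve:
    """A timestamped absorbance trace with its optical metadata.

    times in seconds (strictly increasing, ≥ 5 points), absorbance in AU,
    epsilon in M⁻¹cm⁻¹, pathlength in cm.
    """

    times: np.ndarray
    absorbance: np.ndarray
    epsilon: float
    pathlength: float = 1.0
    wavelength: float = 340.0
    well_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "absorbance", a)
        if t.ndim != 1 or a.shape != t.shape:
            raise ValueError("times and absorbance must be 1-D arrays of equal length")
        if t.size < 5:
            raise ValueError(f"progress curve needs ≥ 5 time points, got {t.size}")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (self.epsilon > 0):
            raise ValueError(f"extinction coefficient must be positive, got {self.epsilon}")
        if not (self.pathlength > 0):
            raise ValueError(f"pathlength must be positive, got {self.pathlength}")


@dataclass(frozen=True)
class InitialRate:
    """An extracted initial rate (µM·s⁻¹, positive = substrate consumption)."""

    rate: float
    window: Tuple[int, int]
    r_squared: float
    flag: str = ACCEPTED
    well_id: str = ""

    @property
    def accepted(self) -> bool:
        return self.flag == ACCEPTED


def absorbance_to_concentration(curve: ProgressCurve) -> np.ndarray:
    """Beer-Lambert conversion of the trace to µM: c = A/(ε·l) × 10⁶."""
    return curve.absorbance / (curve.epsilon * curve.pathlength) * 1e6


def extract_initial_rate(
    curve: ProgressCurve,
    max_consumed_frac: float = 0.10,
    min_points: int = 5,
    blank: Optional[ProgressCurve] = None,
) -> InitialRate:
    """Initial-linear-window rate estimate from a decaying absorbance trace.

    The fitting window is the longest prefix of the trace in which the
    consumed substrate (initial minus current concentration) stays within
    ``max_consumed_frac`` of the initial concentration and which holds at
    least ``min_points`` readings.  The rate is minus the OLS slope of
    concentration vs time, so substrate consumption is positive.

    An optional paired ``blank`` (enzyme-free) trace on the same time base is
    subtracted before conversion, removing background drift.  Degenerate
    traces (too short a window, or no signal variance) return a rejected
    result rather than raising.
    """
    if not (0 < max_consumed_frac < 1):
        raise ValueError("max_consumed_frac must lie in (0, 1)")
    absorbance = curve.absorbance
    if blank is not None:
        if blank.times.shape != curve.times.shape or np.any(blank.times != curve.times):
            raise ValueError("blank trace must share the sample's time base")
        absorbance = absorbance - blank.absorbance
        curve = ProgressCurve(
            curve.times, absorbance, curve.epsilon, curve.pathlength,
            curve.wavelength, curve.well_id,
        )

    conc = absorbance_to_concentration(curve)
    c0 = conc[0]
    consumed = c0 - conc
    limit = max_consumed_frac * abs(c0) if c0 != 0 else np.inf

    # longest prefix with consumption within the limit
    over = np.nonzero(consumed > limit)[0]
    end = over[0] if over.size else conc.size
    if end < min_points:
        return InitialRate(0.0, (0, int(end)), np.nan, REJECTED, curve.well_id)

    t_w = curve.times[:end]
    c_w = conc[:end]
    ss_tot = float(np.sum((c_w - c_w.mean()) ** 2))
    if ss_tot == 0.0:
        # constant trace: no measurable change
        return InitialRate(0.0, (0, int(end)), np.nan, REJECTED, curve.well_id)

    slope, intercept = np.polyfit(t_w, c_w, 1)
    resid = c_w - (slope * t_w + intercept)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return InitialRate(float(-slope), (0, int(end)), r2, ACCEPTED, curve.well_id)
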