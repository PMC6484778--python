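"""Orientation selectivity by vector averaging over doubled-angle space.

For responses r(theta) at the 12 drift directions,

    OSI = min(| sum_theta r(theta) e^{2i theta} / sum_theta r(theta) |, 1)

with theta in radians.  OSI is 0 for an untuned (uniform) curve and 1 for a
single-direction response; baseline-subtracted responses can be negative,
which may push the raw ratio above 1 - such values are clamped to 1 and
flagged.  The preferred orientation is half the argument of the same
normalized vector sum; the preferred direction is whichever of the two
sampled drift directions nearest the preferred orientation (and its
opposite) elicits the larger response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass(frozen=True)
class TuningCurve:
    """Responses per drift direction for one measure (Vm0, Vm1 or F0)."""

    thetas: np.ndarray  # deg
    r: np.ndarray  # mV or Hz; may be negative after baseline subtraction
    measure: str = ""

    def __post_init__(self) -> None:
        thetas = np.asarray(self.thetas, dtype=float)
        r = np.asarray(self.r, dtype=float)
        if thetas.shape != r.shape or thetas.ndim != 1:
            raise ValueError("thetas and r must be matching 1-D arrays")
        if thetas.size >= 2:
            gaps = np.diff(np.sort(thetas))
            if not np.allclose(gaps, gaps[0]):
                raise ValueError("directions must be evenly spaced")
        object.__setattr__(self, "thetas", thetas)
        object.__setattr__(self, "r", r)


@dataclass(frozen=True)
class TuningSummary:
    osi: float
    clamped: bool
    pref_orientation: float  # deg in [0, 180)
    pref_direction: float  # deg in [0, 360)
    response_at_preferred: float


def _vector_ratio(curve: TuningCurve) -> complex:
    th = np.deg2rad(curve.thetas)
    denom = float(np.sum(curve.r))
    if denom <= 0:
        # an untuned or net-negative curve has no meaningful vector average
        raise ZeroDivisionError("sum of responses is not positive")
    return complex(np.sum(curve.r * np.exp(2j * th)) / denom)


def osi(curve: TuningCurve) -> tuple[float, bool]:
    """Orientation selectivity index and whether clamping at 1 occurred.

    Returns ``(nan, False)`` for curves whose responses sum to <= 0, where
    the normalized vector average is undefined; callers flag such cells.
    """
    try:
        z = _vector_ratio(curve)
    except ZeroDivisionError:
        return float("nan"), False
    mag = abs(z)
    if mag > 1.0:
        return 1.0, True
    return float(mag), False


def preferred_orientation(curve: TuningCurve) -> float:
    """Half the argument of the normalized vector sum, mapped into [0, 180).

    NaN when the vector sum is zero (perfectly untuned) or the response sum
    is not positive.
    """
    try:
        z = _vector_ratio(curve)
    except ZeroDivisionError:
        return float("nan")
    if abs(z) < 1e-12:
        return float("nan")
    ang = 0.5 * np.angle(z)  # radians, in (-pi/2, pi/2]
    deg = np.rad2deg(ang) % 180.0
    return float(deg)


def _nearest_direction(target: float, thetas: np.ndarray) -> float:
    """Sampled direction circularly closest to ``target``; ties -> smaller."""
    target = target % 360.0
    d = np.abs((thetas - target + 180.0) % 360.0 - 180.0)
    best = d.min()
    candidates = thetas[np.isclose(d, best)]
    return float(candidates.min())


def preferred_direction(curve: TuningCurve, pref_orientation_deg: float) -> float:
    """Of the two drift directions flanking the preferred orientation, the
    one with the larger response; exact ties resolve to the smaller angle."""
    if not np.isfinite(pref_orientation_deg):
        return float("nan")
    c1 = _nearest_direction(pref_orientation_deg, curve.thetas)
    c2 = _nearest_direction(pref_orientation_deg + 180.0, curve.thetas)
    r1 = float(curve.r[np.isclose(curve.thetas, c1)][0])
    r2 = float(curve.r[np.isclose(curve.thetas, c2)][0])
    if np.isclose(r1, r2):
        return min(c1, c2)
    return c1 if r1 > r2 else c2


def summarize_tuning(curve: TuningCurve) -> Optional[TuningSummary]:
    """OSI + preferred orientation/direction; None when undefined (flagged
    upstream).  ``response_at_preferred`` is read off the curve."""
    val, clamped = osi(curve)
    if not np.isfinite(val):
        return None
    po = preferred_orientation(curve)
    if not np.isfinite(po):
        return None
    pd = preferred_direction(curve, po)
    r_at = float(curve.r[np.isclose(curve.thetas, pd)][0])
    return TuningSummary(osi=val, clamped=clamped, pref_orientation=po,
                         pref_direction=pd, response_at_preferred=r_at)
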