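"""Contour measurements: the multiple-MRD1s profile and the marginal peak point.

Both measurements operate on a normalized eyelid margin (mm,
pupil-centered, temporal-positive, y-up; see
:mod:`lidcontour.normalize`).

**Multiple MRD1s** samples the vertical height of the upper-lid margin
at ten fixed horizontal positions: every 2 mm from 8 mm nasal to 10 mm
temporal of the pupil center (labels N8 ... N2, MRD1, T2 ... T10). The
height at x = 0 is the classic MRD1. Positions outside the traced
margin's support are reported as missing (NaN), never extrapolated.

**Marginal peak point** idealizes the manual procedure of raising a
horizontal ruler until it is tangent to the lid margin: the peak is the
global maximum of the margin polyline, with x signed
temporal-positive (negative = nasal of the mid-pupillary line).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annot_model import PROFILE_COLUMNS
from .normalize import NormalizedEye

#: Sampling positions in mm relative to the pupil center (nasal negative).
GRID_X = np.array([-8.0, -6.0, -4.0, -2.0, 0.0, 2.0, 4.0, 6.0, 8.0, 10.0])

#: Labels matching GRID_X, nasal to temporal; "MRD1" is x = 0.
GRID_LABELS = PROFILE_COLUMNS

#: Missing heights are NaN.
MISSING = float("nan")

# plateau membership tolerance for peak detection (mm)
_PEAK_TOL = 1e-6


@dataclass(frozen=True)
class ContourProfile:
    """Heights (mm) of the lid margin at the 10 grid positions; NaN = missing."""

    values: np.ndarray = field(default_factory=lambda: np.full(10, np.nan))

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (10,):
            raise ValueError("a contour profile has exactly 10 heights")
        object.__setattr__(self, "values", v)

    @property
    def mrd1(self) -> float:
        """Height at x = 0, the margin reflex distance (NaN if missing)."""
        return float(self.values[4])

    def as_dict(self) -> dict[str, float]:
        return {lab: float(v) for lab, v in zip(GRID_LABELS, self.values)}

    @classmethod
    def from_dict(cls, heights: dict[str, float]) -> "ContourProfile":
        return cls(np.array([heights.get(lab, np.nan) for lab in GRID_LABELS], dtype=float))


@dataclass(frozen=True)
class PeakPoint:
    """Marginal peak point in mm; x < 0 means the peak sits nasal of the pupil."""

    x_mm: float
    y_mm: float


def height_at(eye: NormalizedEye, x: float) -> float:
    """Margin height at horizontal position ``x`` by linear interpolation.

    Returns NaN when ``x`` falls outside the margin polyline's support.
    """
    xs, ys = eye.margin[:, 0], eye.margin[:, 1]
    if x < xs[0] or x > xs[-1]:
        return MISSING
    return float(np.interp(x, xs, ys))


def multiple_mrd1s(eye: NormalizedEye) -> ContourProfile:
    """Sample the margin at the 10-position grid (the multiple-MRD1s profile)."""
    return ContourProfile(np.array([height_at(eye, x) for x in GRID_X]))


def mrd1(profile: ContourProfile) -> float:
    """The x = 0 entry of a profile (NaN if missing)."""
    return profile.mrd1


def peak_point(eye: NormalizedEye) -> PeakPoint:
    """Locate the marginal peak: the highest point of the margin polyline.

    For a piecewise-linear margin the maximum is attained on a vertex.
    If the maximum is shared by a plateau (heights within 1e-6 mm of the
    maximum spanning more than the tolerance in x), the reported x is
    the midpoint of the widest contact interval; the manual tangent
    procedure assumes a unique contact point and leaves ties undefined.
    """
    return polyline_peak(eye.margin[:, 0], eye.margin[:, 1])


def polyline_peak(xs: np.ndarray, ys: np.ndarray) -> PeakPoint:
    """Peak of an arbitrary polyline given as sorted x and heights y."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 2:
        raise ValueError("polyline needs at least 2 vertices")
    y_max = float(np.max(ys))
    at_max = ys >= y_max - _PEAK_TOL
    # contiguous runs of near-max vertices; pick the widest in x
    idx = np.flatnonzero(at_max)
    runs: list[tuple[int, int]] = []
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            runs.append((start, prev))
            start = i
        prev = i
    runs.append((start, prev))
    widths = [xs[b] - xs[a] for a, b in runs]
    a, b = runs[int(np.argmax(widths))]
    x_peak = (xs[a] + xs[b]) / 2.0
    return PeakPoint(x_mm=float(x_peak), y_mm=y_max)


def profile_from_pairs(heights: "list[float] | np.ndarray") -> ContourProfile:
    """Build a profile directly from 10 heights in N8..T10 order."""
    return ContourProfile(np.asarray(heights, dtype=float))


def polyline_through_profile(profile: ContourProfile) -> tuple[np.ndarray, np.ndarray]:
    """The piecewise-linear contour through a profile's (position, height) pairs.

    Missing positions are dropped. Useful for treating published
    group-mean profiles as contours in their own right.
    """
    ok = np.isfinite(profile.values)
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-missing heights to form a polyline")
    return GRID_X[ok], profile.values[ok]
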