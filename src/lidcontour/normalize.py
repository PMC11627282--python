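"""Geometric normalization of raw pixel annotations.

Raw landmarks live in image pixels with the head possibly tilted and an
unknown magnification. Normalization produces, per eye, a margin
polyline in a canonical frame:

* **tilt-free** -- the image is rigidly rotated so the inter-canthal
  line (lateral canthus to lateral canthus) is horizontal;
* **millimetre-scaled** -- pixel distances are calibrated by the
  horizontal corneal white-to-white diameter, taken as 11.77 mm in men
  and 11.64 mm in women;
* **pupil-centered, y-up** -- the pupil center is the origin and
  heights above it are positive (raster y-down is flipped here, once);
* **temporal-positive** -- the x axis points temporally, determined per
  eye by the side of the lateral canthus relative to the pupil, so that
  nasal positions carry negative x for either eye.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .annot_model import WTW_MM, EyeAnnotation, PhotoAnnotation, Point2D


@dataclass(frozen=True)
class NormalizedEye:
    """One eyelid margin in the pupil-centered, mm-scaled, temporal-positive frame.

    ``margin`` is an (n, 2) array of (x, y) mm with strictly increasing x.
    """

    side: str
    margin: np.ndarray
    scale_mm_per_px: float
    tilt_deg: float
    canthus_x_mm: float

    def __post_init__(self) -> None:
        m = np.asarray(self.margin, dtype=float)
        object.__setattr__(self, "margin", m)
        if m.ndim != 2 or m.shape[1] != 2 or m.shape[0] < 2:
            raise ValueError("margin must be an (n>=2, 2) array")
        if not np.all(np.diff(m[:, 0]) > 0):
            raise ValueError("margin x must be strictly increasing")
        if not self.scale_mm_per_px > 0:
            raise ValueError("scale_mm_per_px must be positive")


def tilt_angle(photo: PhotoAnnotation) -> float:
    """Signed head-tilt angle (degrees) of the inter-canthal line.

    The angle is measured from the image horizontal to the line joining
    the two lateral canthi, in raster coordinates, normalized to
    (-90, 90]. Rotating the photo by its negation (see
    :func:`apply_rotation`) levels the canthal line.
    """
    r = photo.eyes["right"].lateral_canthus
    l = photo.eyes["left"].lateral_canthus
    dx, dy = l.x - r.x, l.y - r.y
    if dx == 0 and dy == 0:
        raise ValueError("lateral canthi coincide; tilt is undefined")
    ang = math.degrees(math.atan2(dy, dx))
    # fold to (-90, 90]: direction of the canthal line, not its orientation
    if ang <= -90:
        ang += 180
    elif ang > 90:
        ang -= 180
    return ang


def _rotate_points(pts: np.ndarray, center: np.ndarray, angle_deg: float) -> np.ndarray:
    th = math.radians(angle_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    return (pts - center) @ rot.T + center


def apply_rotation(photo: PhotoAnnotation, angle_deg: float) -> PhotoAnnotation:
    """Rigidly rotate every landmark of both eyes by ``-angle_deg``.

    The rotation center is the inter-canthal midpoint; any center gives
    the same result after pupil-centering, this one keeps both eyes
    symmetric in frame. Pairwise distances are preserved exactly.
    """
    if not math.isfinite(angle_deg):
        raise ValueError("rotation angle must be finite")
    r = photo.eyes["right"].lateral_canthus
    l = photo.eyes["left"].lateral_canthus
    center = np.array([(r.x + l.x) / 2.0, (r.y + l.y) / 2.0])

    def rot_point(p: Point2D) -> Point2D:
        out = _rotate_points(np.array([[p.x, p.y]]), center, -angle_deg)[0]
        return Point2D(x=float(out[0]), y=float(out[1]))

    new_eyes = {}
    for side, eye in photo.eyes.items():
        new_eyes[side] = eye.model_copy(
            update={
                "pupil_center": rot_point(eye.pupil_center),
                "limbus_nasal": rot_point(eye.limbus_nasal),
                "limbus_temporal": rot_point(eye.limbus_temporal),
                "lateral_canthus": rot_point(eye.lateral_canthus),
                "margin": tuple(rot_point(p) for p in eye.margin),
            }
        )
    return photo.model_copy(update={"eyes": new_eyes})


def mm_scale(eye: EyeAnnotation, sex: str) -> float:
    """Metric calibration: mm per pixel from the white-to-white diameter.

    Returns ``wtw(sex) / |limbus_temporal - limbus_nasal|`` with the
    sex-specific white-to-white constant (11.77 mm male, 11.64 mm female).
    """
    if sex not in WTW_MM:
        raise ValueError(f"unknown sex {sex!r}; expected 'male' or 'female'")
    d = math.dist(eye.limbus_nasal.as_tuple(), eye.limbus_temporal.as_tuple())
    if d == 0:
        raise ValueError("limbus points coincide; cannot calibrate")
    return WTW_MM[sex] / d


def to_pupil_frame(
    eye: EyeAnnotation, scale: float, tilt_deg: float = 0.0
) -> NormalizedEye:
    """Map a tilt-corrected eye into the pupil-centered mm frame.

    Margin pixels become ``(p - pupil_center) * scale`` with y negated
    (y-up); the x axis is flipped if needed so the lateral canthus sits
    at positive x (temporal-positive). The margin is then sorted by x
    and consecutive duplicate x collapsed to their mean y; the result
    must contain at least two distinct x.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    c = np.array(eye.pupil_center.as_tuple())
    pts = np.array([p.as_tuple() for p in eye.margin], dtype=float)
    rel = (pts - c) * scale
    rel[:, 1] *= -1.0  # raster y-down -> y-up

    canthus_x = (eye.lateral_canthus.x - eye.pupil_center.x) * scale
    if canthus_x == 0:
        raise ValueError("lateral canthus is directly above/below the pupil; temporal axis undefined")
    s = 1.0 if canthus_x > 0 else -1.0
    rel[:, 0] *= s

    order = np.argsort(rel[:, 0], kind="stable")
    rel = rel[order]
    # collapse runs of (near-)identical x to their mean y
    xs, ys = rel[:, 0], rel[:, 1]
    keep_x: list[float] = []
    keep_y: list[float] = []
    i = 0
    while i < len(xs):
        j = i + 1
        while j < len(xs) and xs[j] - xs[i] < 1e-9:
            j += 1
        keep_x.append(float(xs[i:j].mean()))
        keep_y.append(float(ys[i:j].mean()))
        i = j
    if len(keep_x) < 2:
        raise ValueError("margin has fewer than 2 distinct x positions after preprocessing")
    margin = np.column_stack([keep_x, keep_y])

    return NormalizedEye(
        side=eye.side,
        margin=margin,
        scale_mm_per_px=float(scale),
        tilt_deg=float(tilt_deg),
        canthus_x_mm=float(abs(canthus_x)),
    )


def normalize_photo(
    photo: PhotoAnnotation, calibration: str = "per-eye"
) -> dict[str, NormalizedEye]:
    """Full normalization of one photo: tilt, scale, pupil frame, both eyes.

    ``calibration`` selects the white-to-white source: ``"per-eye"``
    uses each eye's own limbus pair; ``"mean"`` averages the two eyes'
    scales (useful when one limbus is poorly visible).
    """
    if calibration not in ("per-eye", "mean"):
        raise ValueError("calibration must be 'per-eye' or 'mean'")
    tilt = tilt_angle(photo)
    level = apply_rotation(photo, tilt)
    scales = {side: mm_scale(eye, photo.sex) for side, eye in level.eyes.items()}
    if calibration == "mean":
        avg = float(np.mean(list(scales.values())))
        scales = {side: avg for side in scales}
    return {
        side: to_pupil_frame(eye, scales[side], tilt_deg=tilt)
        for side, eye in level.eyes.items()
    }
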