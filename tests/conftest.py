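import numpy as np
import pytest

from lidcontour import (
    ContourProfile,
    EyeAnnotation,
    NormalizedEye,
    PhotoAnnotation,
    Point2D,
)

# Published group-mean margin heights (mm) at the ten grid positions
# N8..T10 for a unilateral-ptosis cohort treated by external levator
# advancement: the ptotic eyelid before and after surgery and the
# non-ptotic fellow eyelid. Used as worked examples throughout the suite.
ELA_GROUP_MEANS = {
    "preop": [0.08, 0.75, 1.20, 1.40, 1.46, 1.29, 0.90, 0.39, -0.24, -1.14],
    "postop": [0.23, 1.23, 1.90, 2.34, 2.43, 2.19, 1.72, 0.93, 0.02, -1.0],
    "fellow": [0.61, 1.64, 2.31, 2.82, 2.88, 2.78, 2.51, 1.90, 1.06, -0.17],
}


def eye_from_polyline(xs, ys, side="right"):
    """NormalizedEye built directly from mm polyline vertices."""
    return NormalizedEye(
        side=side,
        margin=np.column_stack([np.asarray(xs, float), np.asarray(ys, float)]),
        scale_mm_per_px=0.1,
        tilt_deg=0.0,
        canthus_x_mm=float(np.max(xs)) + 1.0,
    )


def profile(values) -> ContourProfile:
    return ContourProfile(np.asarray(values, float))


def simple_eye(side="right", pupil=(300.0, 200.0), mirror=False):
    """Hand-built pixel-space eye annotation with a parabolic margin.

    ``mirror`` flips the temporal direction in image x (right eye default
    layout has temporal toward smaller x, as in a frontal photo).
    """
    s = -1.0 if (side == "right") != mirror else 1.0
    px, py = pupil
    scale = 10.0  # px per mm
    xs_mm = np.linspace(-12.0, 14.0, 53)
    ys_mm = 2.5 - 0.03 * xs_mm**2
    margin = tuple(
        Point2D(x=px + s * x * scale, y=py - y * scale) for x, y in zip(xs_mm, ys_mm)
    )
    return EyeAnnotation(
        side=side,
        pupil_center=Point2D(x=px, y=py),
        limbus_nasal=Point2D(x=px - s * 58.85, y=py),
        limbus_temporal=Point2D(x=px + s * 58.85, y=py),
        lateral_canthus=Point2D(x=px + s * 140.0, y=py + 5.0),
        margin=margin,
        pupil_diameter=40.0,
    )


@pytest.fixture
def photo() -> PhotoAnnotation:
    """A minimal valid two-eye annotation (both eyes level, no tilt)."""
    return PhotoAnnotation(
        patient_id="p001",
        timepoint="preop",
        sex="male",
        ptotic_side="right",
        eyes={
            "right": simple_eye("right", pupil=(300.0, 200.0)),
            "left": simple_eye("left", pupil=(900.0, 200.0)),
        },
    )
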