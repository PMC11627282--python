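"""Synthetic eyelid cohorts with exact ground truth.

No photographs are deposited with ptosis-surgery studies of this kind,
so every pipeline stage is exercised against generated data instead.
The generator emulates the study's acquisition chain:

* an analytic upper-lid margin -- a piecewise parabola with independent
  nasal and temporal curvatures, the simplest family that reproduces an
  asymmetrically drooped arch (this is a test harness, not a claim
  about real lid mechanics);
* a surgical elevation applied to it, either **uniform** (every point
  raised equally, the "dome tent" behaviour attributed to Muller's
  muscle conjunctival resection) or **center-weighted** (a Gaussian
  taper around the suture point, the "bell tent" behaviour attributed
  to external levator advancement);
* projection to image pixels at a configurable scale, a global head
  tilt, and Gaussian annotation noise on landmarks and on the traced
  margin -- returning both the noisy annotation and the exact analytic
  ground truth (profile and peak).

All randomness flows from a single master seed; per-patient sub-streams
are spawned with ``numpy.random.SeedSequence`` so any one patient is
reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal, Optional

import numpy as np
import pandas as pd

from .annot_model import (
    WTW_MM,
    EyeAnnotation,
    PhotoAnnotation,
    Point2D,
    save_photo_annotation,
)
from .contour_metrics import GRID_X, ContourProfile, PeakPoint


@dataclass(frozen=True)
class ContourParams:
    """Piecewise-parabolic lid margin: y = peak_y - c_side * (x - peak_x)^2.

    ``curv_nasal`` applies nasal of the peak (x < peak_x), ``curv_temporal``
    temporal of it; the contour is defined on
    [canthus_nasal_x, canthus_temporal_x] (mm, pupil-centered,
    temporal-positive).
    """

    peak_x: float = 0.0
    peak_y: float = 3.0
    curv_nasal: float = 0.036
    curv_temporal: float = 0.028
    canthus_nasal_x: float = -13.0
    canthus_temporal_x: float = 15.0

    def __post_init__(self) -> None:
        if not (self.curv_nasal > 0 and self.curv_temporal > 0):
            raise ValueError("curvatures must be positive")
        if not (self.canthus_nasal_x < 0 < self.canthus_temporal_x):
            raise ValueError("nasal canthus must lie at negative x, temporal at positive x")
        if not (self.canthus_nasal_x < self.peak_x < self.canthus_temporal_x):
            raise ValueError("peak_x must lie inside the contour support")

    def height(self, x: "float | np.ndarray") -> "float | np.ndarray":
        x = np.asarray(x, dtype=float)
        c = np.where(x < self.peak_x, self.curv_nasal, self.curv_temporal)
        y = self.peak_y - c * (x - self.peak_x) ** 2
        return float(y) if y.ndim == 0 else y


@dataclass(frozen=True)
class SurgeryModel:
    """Additive lid elevation applied by a repair.

    ``uniform`` raises every margin point by ``effect_mm``;
    ``center_weighted`` raises by
    ``effect_mm * exp(-(x - center_x)^2 / (2 * taper_width_mm^2))``,
    strongest at the suture point and fading toward the canthi.
    """

    kind: Literal["uniform", "center_weighted"]
    effect_mm: float
    taper_width_mm: float = 5.0
    center_x: float = 0.0

    def __post_init__(self) -> None:
        if self.effect_mm < 0:
            raise ValueError("effect_mm must be >= 0")
        if self.kind == "center_weighted" and not self.taper_width_mm > 0:
            raise ValueError("taper_width_mm must be positive")
        if self.kind not in ("uniform", "center_weighted"):
            raise ValueError(f"unknown surgery kind {self.kind!r}")

    def elevation(self, x: "float | np.ndarray") -> "float | np.ndarray":
        x = np.asarray(x, dtype=float)
        if self.kind == "uniform":
            e = np.full_like(x, self.effect_mm)
        else:
            e = self.effect_mm * np.exp(
                -((x - self.center_x) ** 2) / (2.0 * self.taper_width_mm**2)
            )
        return float(e) if e.ndim == 0 else e


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition and annotation noise for one synthetic photograph.

    ``landmark_sd_px`` perturbs point landmarks (pupil center, limbi,
    canthi) isotropically in pixels; ``margin_sd_mm`` perturbs each
    traced margin vertex vertically in mm; ``tilt_deg`` is the head
    tilt baked into the photo; ``scale_px_per_mm`` the magnification.
    """

    landmark_sd_px: float = 0.0
    margin_sd_mm: float = 0.0
    tilt_deg: float = 0.0
    scale_px_per_mm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.landmark_sd_px < 0 or self.margin_sd_mm < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not self.scale_px_per_mm > 0:
            raise ValueError("scale_px_per_mm must be positive")


@dataclass(frozen=True)
class SyntheticContour:
    """An analytic margin height function plus its support and exact peak."""

    height: Callable[[np.ndarray], np.ndarray]
    support: tuple[float, float]
    peak: PeakPoint

    def sample(self, n_points: int = 400) -> tuple[np.ndarray, np.ndarray]:
        """Polyline vertices: uniform in x, plus the grid positions and the
        exact peak so those points are vertex-exact under linear
        interpolation."""
        if n_points < 10:
            raise ValueError("n_points must be >= 10")
        lo, hi = self.support
        xs = np.linspace(lo, hi, n_points)
        extras = np.array([x for x in GRID_X if lo <= x <= hi] + [self.peak.x_mm])
        # keep inserted exact positions well separated from uniform samples:
        # near the peak the contour is flat, and a vertex closer than
        # ~sqrt(tol/curvature) would merge with it into a spurious plateau
        far = np.abs(xs[:, None] - extras[None, :]).min(axis=1) > 1e-2
        xs = np.unique(np.concatenate([xs[far], extras]))
        return xs, np.asarray(self.height(xs), dtype=float)

    def true_profile(self) -> ContourProfile:
        """Analytic heights at the 10 grid positions (NaN outside support)."""
        lo, hi = self.support
        vals = np.array(
            [self.height(x) if lo <= x <= hi else np.nan for x in GRID_X], dtype=float
        )
        return ContourProfile(vals)


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-eye measurements a perfect pipeline should recover."""

    profiles: dict[str, ContourProfile]
    peaks: dict[str, PeakPoint]


def make_contour(params: ContourParams, n_points: int = 400) -> SyntheticContour:
    """Wrap contour parameters into a sampled/analytic contour object."""
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    return SyntheticContour(
        height=params.height,
        support=(params.canthus_nasal_x, params.canthus_temporal_x),
        peak=PeakPoint(x_mm=params.peak_x, y_mm=params.peak_y),
    )


def _argmax_on_support(fn: Callable, lo: float, hi: float) -> tuple[float, float]:
    """Global maximum of a smooth unimodal-ish function: dense scan + golden refine."""
    from scipy.optimize import minimize_scalar

    xs = np.linspace(lo, hi, 2001)
    ys = np.asarray(fn(xs), dtype=float)
    i = int(np.argmax(ys))
    a = xs[max(i - 1, 0)]
    b = xs[min(i + 1, len(xs) - 1)]
    res = minimize_scalar(lambda x: -float(fn(np.asarray(x))), bounds=(a, b), method="bounded",
                          options={"xatol": 1e-10})
    x_star = float(res.x)
    candidates = [(x_star, float(fn(np.asarray(x_star)))), (xs[i], float(ys[i]))]
    x_best, y_best = max(candidates, key=lambda t: t[1])
    return x_best, y_best


def apply_surgery(
    contour: "SyntheticContour | ContourParams", model: SurgeryModel
) -> SyntheticContour:
    """Postoperative contour: pointwise sum of the margin and the elevation."""
    if isinstance(contour, ContourParams):
        contour = make_contour(contour)
    base = contour.height

    def lifted(x: np.ndarray) -> np.ndarray:
        return np.asarray(base(x), dtype=float) + np.asarray(model.elevation(x), dtype=float)

    lo, hi = contour.support
    if model.kind == "uniform":
        peak = PeakPoint(contour.peak.x_mm, contour.peak.y_mm + model.effect_mm)
    else:
        x_star, y_star = _argmax_on_support(lifted, lo, hi)
        peak = PeakPoint(x_star, y_star)
    return SyntheticContour(height=lifted, support=(lo, hi), peak=peak)


# ---------------------------------------------------------------------------
# photograph synthesis


def _image_temporal_sign(side: str) -> float:
    # frontal photo: the patient's right eye appears on the image left,
    # so its temporal direction points toward smaller image x
    return 1.0 if side == "left" else -1.0


#: mm the lateral canthus sits below the pupil-center line in the
#: untilted head (shared by both eyes; the inter-canthal line is the
#: tilt reference, so it must be level at zero tilt).
CANTHUS_DROP_MM = 0.5

#: anatomical inter-pupillary distance used for the synthetic face (mm)
INTERPUPIL_MM = 60.0


def synth_photo(
    contours: dict[str, SyntheticContour],
    noise: NoiseModel,
    sex: str,
    ptotic_side: str,
    timepoint: str,
    patient_id: str = "synthetic",
    n_margin_points: int = 400,
    rng: Optional[np.random.Generator] = None,
) -> tuple[PhotoAnnotation, GroundTruth]:
    """Render contours of both eyes into a pixel-space photo annotation.

    ``contours`` maps each side ("right"/"left") to its margin contour in
    the mm pupil frame of that eye. The pixel geometry places the two
    pupils an inter-pupillary distance apart, projects margins, limbi
    (white-to-white apart) and canthi, applies the global head tilt
    about the inter-pupillary midpoint, and finally adds Gaussian
    annotation noise. Returns the annotation plus the exact noise-free
    ground truth per eye.
    """
    if set(contours) != {"right", "left"}:
        raise ValueError("contours must be given for both 'right' and 'left'")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    spx = noise.scale_px_per_mm
    wtw = WTW_MM[sex]

    cx, cy = 640.0, 420.0  # arbitrary image position of the face midline
    pupil_px = {
        "right": np.array([cx - spx * INTERPUPIL_MM / 2, cy]),
        "left": np.array([cx + spx * INTERPUPIL_MM / 2, cy]),
    }

    th = math.radians(noise.tilt_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    center = np.array([cx, cy])

    def place(pts: np.ndarray) -> np.ndarray:
        return (pts - center) @ rot.T + center

    eyes: dict[str, EyeAnnotation] = {}
    truth_profiles: dict[str, ContourProfile] = {}
    truth_peaks: dict[str, PeakPoint] = {}
    for side, contour in contours.items():
        s = _image_temporal_sign(side)
        pc = pupil_px[side]
        xs_mm, ys_mm = contour.sample(n_margin_points)
        ys_noisy = ys_mm + rng.normal(0.0, noise.margin_sd_mm, size=ys_mm.shape)
        margin_px = np.column_stack([pc[0] + s * xs_mm * spx, pc[1] - ys_noisy * spx])

        lo, hi = contour.support
        landmarks = {
            "pupil_center": pc.copy(),
            "limbus_nasal": np.array([pc[0] - s * wtw / 2 * spx, pc[1]]),
            "limbus_temporal": np.array([pc[0] + s * wtw / 2 * spx, pc[1]]),
            "lateral_canthus": np.array([pc[0] + s * hi * spx, pc[1] + CANTHUS_DROP_MM * spx]),
        }
        placed = {k: place(v[None, :])[0] for k, v in landmarks.items()}
        margin_placed = place(margin_px)
        for k in placed:
            placed[k] = placed[k] + rng.normal(0.0, noise.landmark_sd_px, size=2)

        eyes[side] = EyeAnnotation(
            side=side,
            pupil_center=Point2D(x=placed["pupil_center"][0], y=placed["pupil_center"][1]),
            limbus_nasal=Point2D(x=placed["limbus_nasal"][0], y=placed["limbus_nasal"][1]),
            limbus_temporal=Point2D(
                x=placed["limbus_temporal"][0], y=placed["limbus_temporal"][1]
            ),
            lateral_canthus=Point2D(
                x=placed["lateral_canthus"][0], y=placed["lateral_canthus"][1]
            ),
            margin=tuple(Point2D(x=float(p[0]), y=float(p[1])) for p in margin_placed),
            pupil_diameter=4.0 * spx,
        )
        truth_profiles[side] = contour.true_profile()
        truth_peaks[side] = contour.peak

    photo = PhotoAnnotation(
        patient_id=patient_id,
        timepoint=timepoint,
        sex=sex,
        ptotic_side=ptotic_side,
        eyes=eyes,
        metadata={"synthetic": True, "tilt_deg": noise.tilt_deg},
    )
    return photo, GroundTruth(profiles=truth_profiles, peaks=truth_peaks)


# ---------------------------------------------------------------------------
# cohort synthesis

#: Ptotic-eyelid baseline shapes per arm, loosely matched to the study's
#: preoperative group means (nasally displaced low peak for the arm
#: destined for levator advancement; central low peak for the
#: Muller's-muscle arm) and the non-ptotic fellow eyelid.
DEFAULT_PTOTIC_ELA = ContourParams(peak_x=-1.2, peak_y=1.6, curv_nasal=0.033, curv_temporal=0.022)
DEFAULT_PTOTIC_MMCR = ContourParams(peak_x=0.0, peak_y=1.2, curv_nasal=0.033, curv_temporal=0.022)
DEFAULT_FELLOW = ContourParams(peak_x=-0.3, peak_y=3.0, curv_nasal=0.036, curv_temporal=0.028)

DEFAULT_SURGERY = {
    "ELA-like": SurgeryModel(kind="center_weighted", effect_mm=1.0, taper_width_mm=5.0),
    "MMCR-like": SurgeryModel(kind="uniform", effect_mm=1.1),
}

#: Between-patient jitter of contour parameters (sd of additive normal
#: perturbations of peak position, multiplicative log-normal on
#: curvatures), chosen to give baseline MRD1 spreads of the order the
#: study reports (~1 mm).
PEAK_Y_JITTER_SD = 0.8
PEAK_X_JITTER_SD = 0.8
CURV_LOG_JITTER_SD = 0.15
TILT_JITTER_SD = 3.0


@dataclass(frozen=True)
class SyntheticPatient:
    """All generated artefacts for one simulated unilateral-ptosis patient."""

    patient_id: str
    arm: str
    sex: str
    ptotic_side: str
    photo_pre: PhotoAnnotation
    photo_post: PhotoAnnotation
    truth_pre: GroundTruth
    truth_post: GroundTruth
    params_pre: ContourParams
    params_fellow: ContourParams
    seed: int


def _jitter_params(base: ContourParams, rng: np.random.Generator) -> ContourParams:
    return replace(
        base,
        peak_x=base.peak_x + rng.normal(0.0, PEAK_X_JITTER_SD),
        peak_y=base.peak_y + rng.normal(0.0, PEAK_Y_JITTER_SD),
        curv_nasal=base.curv_nasal * math.exp(rng.normal(0.0, CURV_LOG_JITTER_SD)),
        curv_temporal=base.curv_temporal * math.exp(rng.normal(0.0, CURV_LOG_JITTER_SD)),
    )


def synth_cohort(
    n_patients: int,
    arm: Literal["ELA-like", "MMCR-like"],
    base_params: Optional[ContourParams] = None,
    surgery: Optional[SurgeryModel] = None,
    fellow_params: Optional[ContourParams] = None,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    n_margin_points: int = 400,
) -> list[SyntheticPatient]:
    """Simulate a unilateral-ptosis surgical arm of ``n_patients``.

    Per patient: the ptotic-eye baseline contour is a jittered copy of
    ``base_params``; the postoperative contour applies ``surgery`` to
    that same baseline (a paired design); the fellow eye is a jittered
    ``fellow_params``, identical in the pre and post photographs. Each
    photo gets its own head tilt (normal, sd 3 degrees) and fresh
    annotation noise. Sub-seeds derive from ``seed`` via
    ``SeedSequence.spawn`` so patients are independently reproducible.
    """
    if n_patients < 2:
        raise ValueError("a cohort needs at least 2 patients")
    if base_params is None:
        base_params = DEFAULT_PTOTIC_ELA if arm == "ELA-like" else DEFAULT_PTOTIC_MMCR
    if surgery is None:
        surgery = DEFAULT_SURGERY[arm]
    if fellow_params is None:
        fellow_params = DEFAULT_FELLOW
    if noise is None:
        noise = NoiseModel(landmark_sd_px=1.5, margin_sd_mm=0.5, scale_px_per_mm=10.0)

    children = np.random.SeedSequence(seed).spawn(n_patients)
    cohort: list[SyntheticPatient] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        sex = "male" if rng.random() < 0.69 else "female"  # 22 of 32 in the study
        ptotic_side = "right" if rng.random() < 0.5 else "left"
        fellow_side = "left" if ptotic_side == "right" else "right"

        p_pre = _jitter_params(base_params, rng)
        p_fellow = _jitter_params(fellow_params, rng)
        c_pre = make_contour(p_pre)
        c_post = apply_surgery(c_pre, surgery)
        c_fellow = make_contour(p_fellow)

        photos = {}
        truths = {}
        for timepoint, ptotic_contour in (("preop", c_pre), ("postop6m", c_post)):
            tilt = float(rng.normal(0.0, TILT_JITTER_SD))
            nm = replace(noise, tilt_deg=tilt)
            photos[timepoint], truths[timepoint] = synth_photo(
                {ptotic_side: ptotic_contour, fellow_side: c_fellow},
                nm,
                sex=sex,
                ptotic_side=ptotic_side,
                timepoint=timepoint,
                patient_id=f"{arm}-{i:03d}",
                n_margin_points=n_margin_points,
                rng=rng,
            )
        cohort.append(
            SyntheticPatient(
                patient_id=f"{arm}-{i:03d}",
                arm=arm,
                sex=sex,
                ptotic_side=ptotic_side,
                photo_pre=photos["preop"],
                photo_post=photos["postop6m"],
                truth_pre=truths["preop"],
                truth_post=truths["postop6m"],
                params_pre=p_pre,
                params_fellow=p_fellow,
                seed=sub_seed,
            )
        )
    return cohort


def write_cohort(cohort: list[SyntheticPatient], out_dir: str | Path) -> Path:
    """Save a cohort's annotation JSONs plus a manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pat in cohort:
        for timepoint, photo in (("preop", pat.photo_pre), ("postop6m", pat.photo_post)):
            fname = f"{pat.patient_id}_{timepoint}.json"
            save_photo_annotation(photo, out_dir / fname)
            rows.append(
                {
                    "patient_id": pat.patient_id,
                    "arm": pat.arm.replace("-like", ""),
                    "timepoint": timepoint,
                    "annotation_path": fname,
                    "seed": pat.seed,
                    "true_peak_x_pre": pat.params_pre.peak_x,
                    "true_peak_y_pre": pat.params_pre.peak_y,
                }
            )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# optional raster rendering


def render_png(
    photo: PhotoAnnotation, canvas: tuple[int, int], path: Optional[str | Path] = None
):
    """Draw a schematic raster of the annotation (sclera, iris, pupil, margin).

    Purely a fixture generator for exercising image-path plumbing;
    deterministic for identical inputs. Raises if the canvas is empty
    or any landmark falls outside it.
    """
    from PIL import Image, ImageDraw

    w, h = canvas
    if w <= 0 or h <= 0:
        raise ValueError("canvas dimensions must be positive")
    pts = []
    for eye in photo.eyes.values():
        pts += [eye.pupil_center, eye.limbus_nasal, eye.limbus_temporal, eye.lateral_canthus]
        pts += list(eye.margin)
    for p in pts:
        if not (0 <= p.x < w and 0 <= p.y < h):
            raise ValueError(f"landmark ({p.x:.1f}, {p.y:.1f}) outside canvas {canvas}")

    img = Image.new("L", (w, h), color=255)
    draw = ImageDraw.Draw(img)
    for eye in photo.eyes.values():
        cx, cy = eye.pupil_center.x, eye.pupil_center.y
        wtw_px = math.dist(eye.limbus_nasal.as_tuple(), eye.limbus_temporal.as_tuple())
        fissure = math.dist((cx, cy), eye.lateral_canthus.as_tuple()) * 1.8
        draw.ellipse(
            [cx - fissure / 2, cy - wtw_px * 0.55, cx + fissure / 2, cy + wtw_px * 0.55],
            fill=230,
        )
        draw.ellipse(
            [cx - wtw_px / 2, cy - wtw_px / 2, cx + wtw_px / 2, cy + wtw_px / 2], fill=128
        )
        r = (eye.pupil_diameter or wtw_px / 3) / 2
        draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=0)
        draw.line([p.as_tuple() for p in eye.margin], fill=60, width=2)
    if path is not None:
        img.save(path)
    return img
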