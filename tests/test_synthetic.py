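import numpy as np
import pytest

from lidcontour import (
    ContourParams,
    NoiseModel,
    SurgeryModel,
    apply_surgery,
    height_at,
    load_photo_annotation,
    make_contour,
    measure_photo,
    render_png,
    save_photo_annotation,
    synth_cohort,
    synth_photo,
)
from lidcontour.normalize import to_pupil_frame
from lidcontour.synthetic import write_cohort

from conftest import eye_from_polyline


def default_contours():
    c = make_contour(ContourParams())
    return {"right": c, "left": c}


class TestMakeContour:
    def test_symmetric_peak(self):
        c = make_contour(ContourParams(peak_x=0.0, peak_y=3.0, curv_nasal=0.03, curv_temporal=0.03))
        assert c.height(0.0) == 3.0
        assert c.height(4.0) == pytest.approx(c.height(-4.0))

    def test_nasal_peak_location(self):
        c = make_contour(ContourParams(peak_x=-1.18, peak_y=1.59))
        xs = np.linspace(*c.support, 5001)
        assert xs[np.argmax(c.height(xs))] == pytest.approx(-1.18, abs=0.01)
        assert c.peak.x_mm == -1.18 and c.peak.y_mm == 1.59

    def test_polyline_matches_analytic(self):
        c = make_contour(ContourParams())
        xs, ys = c.sample(4000)
        eye = eye_from_polyline(xs, ys)
        rng = np.random.default_rng(1)
        for x in rng.uniform(*c.support, size=100):
            assert height_at(eye, x) == pytest.approx(c.height(x), abs=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ContourParams(curv_nasal=-0.01)
        with pytest.raises(ValueError):
            ContourParams(canthus_nasal_x=2.0)
        with pytest.raises(ValueError):
            ContourParams(peak_x=20.0)


class TestApplySurgery:
    def test_uniform_shifts_everywhere(self):
        c = make_contour(ContourParams())
        lifted = apply_surgery(c, SurgeryModel(kind="uniform", effect_mm=1.0))
        xs = np.linspace(*c.support, 200)
        np.testing.assert_allclose(lifted.height(xs), c.height(xs) + 1.0, atol=1e-12)
        assert lifted.peak.y_mm == pytest.approx(c.peak.y_mm + 1.0)
        assert lifted.peak.x_mm == c.peak.x_mm

    def test_center_weighted_closed_form(self):
        m = SurgeryModel(kind="center_weighted", effect_mm=1.0, taper_width_mm=5.0, center_x=0.0)
        assert m.elevation(0.0) == pytest.approx(1.0)
        assert m.elevation(10.0) == pytest.approx(np.exp(-2.0))

    def test_center_weighted_taper_monotone(self):
        m = SurgeryModel(kind="center_weighted", effect_mm=1.0, taper_width_mm=5.0, center_x=0.5)
        xs = np.linspace(0.5, 15, 500)
        assert np.all(np.diff(m.elevation(xs)) < 0)
        xs = np.linspace(-13, 0.5, 500)
        assert np.all(np.diff(m.elevation(xs)) > 0)

    def test_composite_peak_is_true_maximum(self):
        c = make_contour(ContourParams(peak_x=-1.2, peak_y=1.6))
        lifted = apply_surgery(
            c, SurgeryModel(kind="center_weighted", effect_mm=1.0, taper_width_mm=5.0)
        )
        xs = np.linspace(*c.support, 200001)
        ys = lifted.height(xs)
        assert lifted.peak.y_mm == pytest.approx(float(ys.max()), abs=1e-8)
        assert lifted.peak.x_mm == pytest.approx(float(xs[np.argmax(ys)]), abs=1e-4)
        # the central pull drags the peak temporally toward the suture
        assert c.peak.x_mm < lifted.peak.x_mm < 0


class TestSynthPhoto:
    def test_noise_free_chain_is_exact(self):
        photo, truth = synth_photo(
            default_contours(), NoiseModel(), sex="male", ptotic_side="right",
            timepoint="preop",
        )
        meas = measure_photo(photo)
        for side in ("right", "left"):
            np.testing.assert_allclose(
                meas[side].profile.values, truth.profiles[side].values, atol=1e-6
            )
            assert meas[side].peak.x_mm == pytest.approx(truth.peaks[side].x_mm, abs=1e-6)
            assert meas[side].peak.y_mm == pytest.approx(truth.peaks[side].y_mm, abs=1e-6)

    @pytest.mark.parametrize("tilt,scale", [(7.0, 10.0), (-15.0, 3.0), (12.5, 30.0)])
    def test_tilt_and_scale_invariance(self, tilt, scale):
        nm = NoiseModel(tilt_deg=tilt, scale_px_per_mm=scale)
        photo, truth = synth_photo(
            default_contours(), nm, sex="female", ptotic_side="left", timepoint="postop6m"
        )
        meas = measure_photo(photo)
        for side in ("right", "left"):
            np.testing.assert_allclose(
                meas[side].profile.values, truth.profiles[side].values, atol=1e-6
            )
            assert abs(meas[side].tilt_deg - tilt) < 1e-6

    def test_seeded_annotation_is_byte_identical(self, tmp_path):
        nm = NoiseModel(landmark_sd_px=2.0, margin_sd_mm=0.4, tilt_deg=3.0, seed=77)
        a, _ = synth_photo(default_contours(), nm, sex="male", ptotic_side="right",
                           timepoint="preop")
        b, _ = synth_photo(default_contours(), nm, sex="male", ptotic_side="right",
                           timepoint="preop")
        pa = save_photo_annotation(a, tmp_path / "a.json")
        pb = save_photo_annotation(b, tmp_path / "b.json")
        assert pa.read_bytes() == pb.read_bytes()

    def test_generator_output_roundtrips_identically(self, tmp_path):
        nm = NoiseModel(landmark_sd_px=1.0, margin_sd_mm=0.3, tilt_deg=-4.0, seed=5)
        photo, _ = synth_photo(default_contours(), nm, sex="female", ptotic_side="left",
                               timepoint="preop")
        path = save_photo_annotation(photo, tmp_path / "p.json")
        assert load_photo_annotation(path) == photo


class TestSynthCohort:
    def test_structure_and_schema_validity(self, tmp_path):
        cohort = synth_cohort(4, "MMCR-like", seed=3, n_margin_points=60)
        assert len(cohort) == 4
        manifest = write_cohort(cohort, tmp_path)
        import pandas as pd

        rows = pd.read_csv(manifest)
        assert len(rows) == 8  # 2 photos per patient
        for rel in rows["annotation_path"]:
            loaded = load_photo_annotation(tmp_path / rel)
            assert set(loaded.eyes) == {"right", "left"}

    def test_null_effect_changes_only_by_noise(self):
        cohort = synth_cohort(
            10, "MMCR-like",
            surgery=SurgeryModel(kind="uniform", effect_mm=0.0),
            noise=NoiseModel(margin_sd_mm=0.3, scale_px_per_mm=10.0),
            seed=12, n_margin_points=120,
        )
        diffs = []
        for pat in cohort:
            m_pre = measure_photo(pat.photo_pre)[pat.ptotic_side].profile.values
            m_post = measure_photo(pat.photo_post)[pat.ptotic_side].profile.values
            diffs.append(np.nanmean(m_post - m_pre))
        se = 0.3 * np.sqrt(2) / np.sqrt(10 * 10)
        assert abs(np.mean(diffs)) < 4 * se

    def test_pre_peak_parameter_recovery(self):
        cohort = synth_cohort(24, "ELA-like", seed=9, n_margin_points=120,
                              noise=NoiseModel(scale_px_per_mm=10.0))
        xs = [
            measure_photo(p.photo_pre)[p.ptotic_side].peak.x_mm for p in cohort
        ]
        se = 0.8 / np.sqrt(24)  # between-patient peak-x jitter sd
        assert abs(np.mean(xs) - (-1.2)) < 4 * se

    def test_sub_seed_reproducibility(self):
        a = synth_cohort(3, "ELA-like", seed=4, n_margin_points=60)
        b = synth_cohort(3, "ELA-like", seed=4, n_margin_points=60)
        assert [p.photo_pre for p in a] == [p.photo_pre for p in b]
        assert a[0].seed != a[1].seed


class TestRenderPng:
    def test_render_deterministic_and_centroid(self, tmp_path):
        nm = NoiseModel(scale_px_per_mm=8.0)
        photo, _ = synth_photo(default_contours(), nm, sex="male", ptotic_side="right",
                               timepoint="preop")
        img1 = render_png(photo, (1280, 840))
        img2 = render_png(photo, (1280, 840))
        assert img1.tobytes() == img2.tobytes()

        arr = np.asarray(img1)
        eye = photo.eyes["right"]
        cx, cy = eye.pupil_center.x, eye.pupil_center.y
        r = int(eye.pupil_diameter)  # window comfortably containing the pupil disc
        win = arr[int(cy) - r : int(cy) + r, int(cx) - r : int(cx) + r]
        ys, xs = np.nonzero(win == 0)
        cx_est = xs.mean() + int(cx) - r
        cy_est = ys.mean() + int(cy) - r
        assert abs(cx_est - cx) < 0.5 and abs(cy_est - cy) < 0.5

    def test_empty_canvas_rejected(self, photo):
        with pytest.raises(ValueError, match="canvas"):
            render_png(photo, (0, 100))

    def test_out_of_canvas_landmark_rejected(self, photo):
        with pytest.raises(ValueError, match="outside canvas"):
            render_png(photo, (200, 200))
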