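"""Rule-based effusion/biofilm classification and ear-day aggregation."""

import numpy as np
import pytest

from octme.me_classify import (
    ClassifierParams,
    EarObservation,
    ScanClassification,
    ScatterStats,
    aggregate_ear_day,
    classify_effusion,
    classify_scan,
    detect_biofilm,
    detect_fluid_air_boundary,
    detect_scatterers,
    ear_end_state,
    estimate_noise_floor,
    middle_ear_roi,
)
from octme.phantom import SceneConfig, render_bscan
from octme.thickness_quant import CorrectionParams, compute_profile, summarize_scan
from octme.tm_segment import segment_tm


def segment_and_profile(scan, n_points=80):
    b = segment_tm(scan)
    p = compute_profile(b, CorrectionParams(n_points=n_points))
    return b, p


class TestROI:
    def test_roi_below_posterior(self, clear_phantom):
        scan, _, _ = clear_phantom
        b, _ = segment_and_profile(scan)
        roi = middle_ear_roi(scan, b)
        rows = np.arange(scan.pixels.shape[0])[:, None]
        guarded = rows > (b.posterior + 2)[None, :]
        assert not np.any(roi & ~guarded & np.isfinite(b.posterior)[None, :])

    def test_empty_valid_gives_empty_roi(self, clear_phantom):
        scan, _, _ = clear_phantom
        b, _ = segment_and_profile(scan)
        b.valid[:] = False
        assert middle_ear_roi(scan, b).sum() == 0

    @pytest.mark.parametrize("seed", range(3))
    def test_roi_never_overlaps_membrane(self, default_optics, seed):
        rng = np.random.default_rng(100 + seed)
        scene = SceneConfig(
            tm_thickness_um=float(rng.uniform(22, 35)),
            tilt_deg=float(rng.uniform(40, 52)),
            mee_type=str(rng.choice(["clear", "watery", "dense"])),
            fluid_fill_fraction=1.0,
            seed=200 + seed,
        )
        scan, _ = render_bscan(default_optics, scene)
        b, _ = segment_and_profile(scan)
        roi = middle_ear_roi(scan, b)
        rows = np.arange(scan.pixels.shape[0])[:, None]
        inside_band = (rows >= np.nan_to_num(b.anterior, nan=np.inf)[None, :]) & (
            rows <= np.nan_to_num(b.posterior, nan=-np.inf)[None, :]
        )
        assert not np.any(roi & inside_band)


class TestScatterers:
    def test_clear_scene_no_particles(self, clear_phantom):
        scan, _, _ = clear_phantom
        b, _ = segment_and_profile(scan)
        roi = middle_ear_roi(scan, b)
        stats = detect_scatterers(scan, roi, boundaries=b)
        assert stats.particle_count == 0
        assert stats.foreground_fraction < 0.005

    def test_watery_density_recovered(self, watery_phantom):
        scan, truth, scene = watery_phantom
        b, _ = segment_and_profile(scan)
        roi = middle_ear_roi(scan, b)
        stats = detect_scatterers(scan, roi, boundaries=b)
        area_mm2 = roi.sum() * scan.axial_pitch_um * scan.lateral_pitch_um * 1e-6
        expected = scene.particle_density_per_mm2 * area_mm2
        assert stats.particle_count == pytest.approx(expected, rel=0.30)

    def test_dense_fill_fraction_high(self, dense_phantom):
        scan, _, _ = dense_phantom
        b, _ = segment_and_profile(scan)
        roi = middle_ear_roi(scan, b)
        stats = detect_scatterers(scan, roi, boundaries=b)
        assert stats.foreground_fraction > 0.10

    def test_noise_floor_requires_air(self, clear_phantom):
        scan, _, _ = clear_phantom
        b, _ = segment_and_profile(scan)
        b2 = segment_tm(scan)
        b2.anterior[:] = 2.0  # no air above the membrane
        with pytest.raises(ValueError, match="air"):
            estimate_noise_floor(scan, b2)


class TestFluidBoundary:
    def test_partial_fill_detected_near_truth(self, default_optics):
        scene = SceneConfig(
            tm_thickness_um=28.0, tilt_deg=45.0, mee_type="watery",
            fluid_fill_fraction=0.5, seed=31,
        )
        scan, truth = render_bscan(default_optics, scene)
        b, _ = segment_and_profile(scan)
        roi = middle_ear_roi(scan, b)
        present, row = detect_fluid_air_boundary(scan, roi, b)
        assert present
        assert truth.fluid_boundary_row is not None
        assert row == pytest.approx(truth.fluid_boundary_row, abs=3.0)

    def test_fully_filled_has_no_boundary(self, watery_phantom):
        scan, truth, _ = watery_phantom
        b, _ = segment_and_profile(scan)
        roi = middle_ear_roi(scan, b)
        present, _ = detect_fluid_air_boundary(scan, roi, b)
        assert not present
        assert truth.fluid_boundary_row is None

    def test_clear_scene_has_no_boundary(self, clear_phantom):
        scan, _, _ = clear_phantom
        b, _ = segment_and_profile(scan)
        present, _ = detect_fluid_air_boundary(scan, middle_ear_roi(scan, b), b)
        assert not present


class TestClassifyEffusion:
    def test_truth_triplet_matches(self, clear_phantom, watery_phantom, dense_phantom):
        for (scan, truth, _scene) in (clear_phantom, watery_phantom, dense_phantom):
            b, p = segment_and_profile(scan)
            c = classify_scan(scan, b, p)
            assert c.mee_class == truth.mee_type

    def test_all_quiet_is_clear(self):
        stats = ScatterStats(0, 0.0, 0.2, 0.05, 0.01, 10000)
        assert classify_effusion(stats, False) == "clear"

    def test_boundary_alone_means_watery(self):
        """A fluid-air boundary with zero particles still signals effusion."""
        stats = ScatterStats(0, 0.0, 0.2, 0.05, 0.01, 10000)
        assert classify_effusion(stats, True) == "watery"

    def test_bright_background_is_dense(self):
        stats = ScatterStats(3, 0.05, 5.0, 0.05, 0.01, 10000)
        assert classify_effusion(stats, False) == "dense"


class TestBiofilm:
    def test_thick_irregular_layer_detected(self, default_optics):
        scene = SceneConfig(
            tm_thickness_um=25.0, tilt_deg=45.0, biofilm_mean_um=75.0,
            biofilm_cv=0.3, seed=41,
        )
        scan, _ = render_bscan(default_optics, scene)
        b, p = segment_and_profile(scan)
        summarize_scan(p, CorrectionParams(n_points=80))
        assert detect_biofilm(p, scan, b)

    def test_clean_thin_membrane_negative(self, clear_phantom):
        scan, _, _ = clear_phantom
        b, p = segment_and_profile(scan)
        assert not detect_biofilm(p, scan, b)

    def test_uniform_thickening_negative(self, default_optics):
        """Inflammation without inconsistent thickness is not biofilm."""
        scene = SceneConfig(tm_thickness_um=60.0, tilt_deg=45.0, seed=42)
        scan, _ = render_bscan(default_optics, scene)
        b, p = segment_and_profile(scan)
        assert p.mean_um > 50  # thick enough, but uniform
        assert not detect_biofilm(p, scan, b)


def _cls(mee="clear", biofilm=False, boundary=False):
    return ScanClassification(
        mee_class=mee,
        biofilm_present=biofilm,
        scatter=ScatterStats(0, 0.0, 0.0, 0.05, 0.01, 1000),
        fluid_boundary_present=boundary,
        fluid_boundary_row=None,
    )


def _prof(mean=25.0, sd=1.0, n=100):
    from octme.thickness_quant import ThicknessProfile

    return ThicknessProfile(
        columns=np.arange(1), theta_i_deg=np.zeros(1), theta_t_deg=np.zeros(1),
        d_img_um=np.full(1, mean), d_um=np.full(1, mean), valid=np.ones(1, bool),
        labels={}, mean_um=mean, sd_um=sd, n_points_used=n,
    )


class TestAggregation:
    def test_any_watery_scan_dominates_clear(self):
        results = [(_cls("clear"), _prof())] * 4 + [(_cls("watery"), _prof())]
        obs = aggregate_ear_day(results, "a1", "L", 3, "no_treatment")
        assert obs.mee_class == "watery" and obs.mee_present

    def test_all_clear_is_clear(self):
        results = [(_cls("clear"), _prof())] * 5
        obs = aggregate_ear_day(results, "a1", "L", 3, "control")
        assert obs.mee_class == "clear" and not obs.mee_present

    def test_no_usable_scans_is_blocked(self):
        obs = aggregate_ear_day([(None, None)] * 3, "a1", "L", 3, "control")
        assert obs.blocked and obs.n_scans_used == 0

    def test_presence_monotone_under_added_scans(self):
        base = [(_cls("watery"), _prof())]
        obs1 = aggregate_ear_day(list(base), "a", "L", 1, "control")
        for extra in ("clear", "watery", "dense"):
            obs2 = aggregate_ear_day(base + [(_cls(extra), _prof())], "a", "L", 1, "control")
            assert obs2.mee_present >= obs1.mee_present

    def test_thickness_pooling(self):
        results = [(_cls(), _prof(mean=20.0, sd=0.0)), (_cls(), _prof(mean=30.0, sd=0.0))]
        obs = aggregate_ear_day(results, "a", "L", 0, "control")
        assert obs.thickness_mean_um == pytest.approx(25.0)
        assert obs.thickness_sd_um > 0  # between-scan spread enters the pooled SD


class TestEndState:
    def _obs(self, day, mee=False, bio=False, blocked=False):
        return EarObservation(
            animal="a", ear="L", day=day, group="no_treatment",
            mee_present=mee, biofilm_present=bio, blocked=blocked,
            mee_class="watery" if mee else "clear",
        )

    def test_last_clear(self):
        assert ear_end_state([self._obs(0, mee=True), self._obs(7)]) == "clear"

    def test_last_mee_and_biofilm(self):
        obs = [self._obs(0), self._obs(7, mee=True, bio=True)]
        assert ear_end_state(obs) == "mee_and_biofilm"

    def test_biofilm_only(self):
        assert ear_end_state([self._obs(7, bio=True)]) == "biofilm_only"

    def test_blocked_end_is_excluded(self):
        obs = [self._obs(0, mee=True), self._obs(7, blocked=True)]
        assert ear_end_state(obs) == "excluded"

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            ear_end_state([])
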