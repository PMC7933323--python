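"""Phantom generator: rendering geometry, determinism, scenarios, sidecars."""

import math

import numpy as np
import pytest

from octme.phantom import (
    OM_BASELINE_UM,
    OM_SLOPE_UM_PER_DAY,
    OpticsConfig,
    PhantomGeometryError,
    ScenarioConfig,
    SceneConfig,
    apparent_axial_extent_um,
    read_truth_sidecar,
    render_bscan,
    render_series,
    scenario_day_state,
    write_truth_sidecar,
)

from conftest import measure_band_extent_rows


class TestRenderBScan:
    def test_identity_rendering_no_refraction(self, noiseless_optics):
        # tilt 0, n = 1: a 30 um membrane spans 10 rows at 3 um pitch
        scene = SceneConfig(tm_thickness_um=30.0, tilt_deg=0.0, ri=1.0, seed=0)
        scan, truth = render_bscan(noiseless_optics, scene)
        extent = measure_band_extent_rows(scan, truth)
        assert extent == pytest.approx(10.0, abs=1.0)

    def test_refraction_distortion_rendered(self, noiseless_optics):
        # tilt 60, n = 1.44, d = 30: apparent extent n*d/cos(theta_t) ~ 54.07 um
        scene = SceneConfig(tm_thickness_um=30.0, tilt_deg=60.0, ri=1.44, seed=0)
        scan, truth = render_bscan(noiseless_optics, scene)
        extent_um = measure_band_extent_rows(scan, truth) * noiseless_optics.axial_pitch_um
        assert extent_um == pytest.approx(54.07, abs=noiseless_optics.axial_pitch_um)

    def test_anterior_surface_at_true_tilt(self, noiseless_optics):
        scene = SceneConfig(tm_thickness_um=30.0, tilt_deg=55.0, ri=1.44, seed=0)
        _, truth = render_bscan(noiseless_optics, scene)
        vc = np.flatnonzero(truth.valid)
        drows = np.diff(truth.anterior_row[vc])
        slope_phys = np.mean(drows) * noiseless_optics.axial_pitch_um / noiseless_optics.lateral_pitch_um
        assert math.degrees(math.atan(abs(slope_phys))) == pytest.approx(55.0, abs=0.01)

    @pytest.mark.parametrize("tilt", [0.0, 20.0, 40.0, 55.0, 70.0])
    @pytest.mark.parametrize("ri", [1.0, 1.33, 1.44])
    def test_refraction_consistency(self, noiseless_optics, tilt, ri):
        """Rendered apparent extent equals the closed-form oracle within 1 px."""
        d = 30.0
        scene = SceneConfig(tm_thickness_um=d, tilt_deg=tilt, ri=ri, seed=0)
        scan, truth = render_bscan(noiseless_optics, scene)
        measured_um = measure_band_extent_rows(scan, truth) * noiseless_optics.axial_pitch_um
        theta_t = math.asin(math.sin(math.radians(tilt)) / ri)
        oracle_um = ri * d / math.cos(theta_t)
        assert measured_um == pytest.approx(oracle_um, abs=noiseless_optics.axial_pitch_um)

    def test_apparent_extent_monotone_in_ri_and_tilt(self):
        extents_ri = [apparent_axial_extent_um(30.0, 40.0, ri) for ri in (1.0, 1.2, 1.33, 1.44)]
        assert np.all(np.diff(extents_ri) >= 0)
        extents_tilt = [apparent_axial_extent_um(30.0, t, 1.44) for t in (0, 20, 40, 55, 70)]
        assert np.all(np.diff(extents_tilt) >= 0)

    def test_seeded_determinism(self, default_optics):
        scene = SceneConfig(mee_type="watery", fluid_fill_fraction=1.0, seed=17)
        scan1, _ = render_bscan(default_optics, scene)
        scan2, _ = render_bscan(default_optics, scene)
        assert np.array_equal(scan1.pixels, scan2.pixels)

    def test_geometry_overflow_names_parameter(self):
        optics = OpticsConfig(image_rows=64, image_cols=64)
        scene = SceneConfig(tilt_deg=80.0, tm_thickness_um=100.0)
        with pytest.raises(PhantomGeometryError, match="tilt_deg"):
            render_bscan(optics, scene)

    @pytest.mark.parametrize("biofilm_mean", [0.0, 40.0])
    def test_biofilm_flag_reflects_config(self, noiseless_optics, biofilm_mean):
        scene = SceneConfig(biofilm_mean_um=biofilm_mean, seed=2)
        _, truth = render_bscan(noiseless_optics, scene)
        assert truth.biofilm_present == (biofilm_mean > 0)

    def test_biofilm_band_brighter_than_tm(self, biofilm_phantom):
        scan, truth, scene = biofilm_phantom
        vc = np.flatnonzero(truth.valid)
        c = int(vc[len(vc) // 2])
        theta_t = math.asin(math.sin(math.radians(scene.tilt_deg)) / scene.ri)
        tm_rows = scene.ri * scene.tm_thickness_um / math.cos(theta_t) / 3.0
        a = truth.anterior_row[c]
        total_rows = scene.ri * truth.thickness_um[c] / math.cos(theta_t) / 3.0
        tm_mean = scan.pixels[int(a + 2) : int(a + tm_rows - 1), c].mean()
        bio_mean = scan.pixels[int(a + tm_rows + 2) : int(a + total_rows - 1), c].mean()
        assert bio_mean >= tm_mean

    def test_watery_scene_has_sparse_bright_particles(self, watery_phantom):
        scan, truth, scene = watery_phantom
        vc = np.flatnonzero(truth.valid)
        deep = scan.pixels[800:, vc[0] : vc[-1]]
        frac = float((deep > 0.3).mean())
        assert 0.0 < frac < 0.1  # sparse, not a dense fill

    def test_invariants_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(tm_thickness_um=-1)
        with pytest.raises(ValueError):
            SceneConfig(tilt_deg=88)
        with pytest.raises(ValueError):
            SceneConfig(mee_type="soupy")
        with pytest.raises(ValueError):
            OpticsConfig(speckle_contrast=1.5)
        with pytest.raises(ValueError):
            OpticsConfig(image_rows=10)


class TestScenarios:
    def test_control_series_constant_and_clear(self, noiseless_optics):
        scen = ScenarioConfig(
            scenario="control", days=(0, 1, 2, 3, 4, 5, 7), baseline_um=25.0,
            scans_per_day=1, seed=0,
        )
        series = render_series(noiseless_optics, scen)
        assert len(series) == 7
        for day, scan, truth in series:
            assert truth.mean_thickness_um == pytest.approx(25.0, abs=1e-6)
            assert truth.mee_type == "clear"
            assert not truth.biofilm_present

    def test_om_progression_follows_line(self):
        # slope 4.4 um/day from baseline 30: day 10 -> 74 um
        scen = ScenarioConfig(
            scenario="om_progression", days=(0, 10), baseline_um=30.0,
            slope_um_per_day=4.4, scans_per_day=1, seed=0,
        )
        state = scenario_day_state(scen, 10)
        assert state.total_um == pytest.approx(30.0 + 4.4 * 10)

    def test_default_progression_matches_observed_range(self):
        # defaults emulate growth from ~31 um at day 0 to ~210 um at day 21
        scen = ScenarioConfig(scenario="om_progression", days=(0, 21))
        assert scenario_day_state(scen, 0).total_um == pytest.approx(OM_BASELINE_UM)
        assert scenario_day_state(scen, 21).total_um == pytest.approx(210.0, abs=0.5)
        assert OM_SLOPE_UM_PER_DAY == pytest.approx((210 - 31) / 21)

    def test_biofilm_only_after_onset(self):
        scen = ScenarioConfig(scenario="om_progression", days=(0, 13))
        assert not scenario_day_state(scen, 3).biofilm_present
        assert scenario_day_state(scen, 9).biofilm_present

    def test_responder_curve_rises_drops_rises(self):
        scen = ScenarioConfig(scenario="treated_responder", days=(0, 13))
        t = [scenario_day_state(scen, d).total_um for d in range(14)]
        assert t[4] > t[0] and t[10] < t[4] and t[13] > t[10]

    def test_healing_returns_to_baseline_with_flags_cleared(self):
        scen = ScenarioConfig(scenario="spontaneous_healing", days=(0, 13), baseline_um=28.0)
        end = scenario_day_state(scen, 13)
        assert end.total_um == pytest.approx(28.0)
        assert end.mee_type == "clear" and not end.biofilm_present

    def test_unknown_scenario_lists_valid_names(self):
        with pytest.raises(ValueError, match="om_progression"):
            ScenarioConfig(scenario="nonsense")

    def test_days_must_increase(self):
        with pytest.raises(ValueError):
            ScenarioConfig(days=(0, 2, 2))


class TestTruthSidecar:
    @pytest.mark.parametrize(
        "scene_kwargs",
        [
            {"mee_type": "clear"},
            {"mee_type": "watery", "biofilm_mean_um": 50.0, "fluid_fill_fraction": 0.5},
            {"mee_type": "dense", "fluid_fill_fraction": 1.0},
        ],
    )
    def test_roundtrip(self, tmp_path, noiseless_optics, scene_kwargs):
        scene = SceneConfig(seed=9, **scene_kwargs)
        _, truth = render_bscan(noiseless_optics, scene)
        path = tmp_path / "truth.json"
        write_truth_sidecar(truth, path)
        back = read_truth_sidecar(path)
        np.testing.assert_array_equal(truth.valid, back.valid)
        np.testing.assert_allclose(
            truth.anterior_row[truth.valid], back.anterior_row[back.valid]
        )
        np.testing.assert_allclose(
            truth.thickness_um[truth.valid], back.thickness_um[back.valid]
        )
        assert (truth.tilt_deg, truth.ri, truth.mee_type) == (
            back.tilt_deg, back.ri, back.mee_type,
        )
        assert truth.biofilm_present == back.biofilm_present
        assert truth.fluid_boundary_row == back.fluid_boundary_row
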