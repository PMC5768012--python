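"""DVH, TG-101 table, signed distances, ROM, sparing regression, volumes."""

import numpy as np
import pandas as pd
import pytest

from mrl4d.core import DoseGrid, StructureMask
from mrl4d.metrics import (
    SparingRecord,
    dvh,
    irradiated_volume_reduction,
    proximity_profile,
    rom,
    signed_min_distance,
    sparing_regression,
    tg101_metrics,
)

from conftest import make_grid, sphere_mask

VOX = 0.25 ** 3  # cc


@pytest.fixture(scope="module")
def grid():
    return make_grid(48)


def box_mask(grid, n_voxels, name="S"):
    vox = np.zeros(grid.shape, dtype=bool)
    vox.reshape(-1)[:n_voxels] = True
    return StructureMask(name, vox, grid)


class TestDvh:
    def test_uniform_dose_step_curve(self, grid):
        mask = box_mask(grid, 1000)
        dose = DoseGrid(np.where(mask.voxels, 10.0, 0.0), grid)
        curve = dvh(dose, mask)
        assert curve.v_at(0.0) == pytest.approx(1000 * VOX)
        assert curve.v_at(5.0) == pytest.approx(1000 * VOX)  # 15.625 cc
        assert curve.v_at(10.05) == 0.0

    def test_linear_ramp_half_volume_at_midpoint(self, grid):
        mask = box_mask(grid, 2000)
        vals = np.zeros(grid.shape)
        vals.reshape(-1)[:2000] = np.linspace(0.0, 20.0, 2000)
        curve = dvh(DoseGrid(vals, grid), mask)
        assert curve.v_at(10.0) == pytest.approx(1000 * VOX, abs=2 * 0.1 / 20 * 2000 * VOX)

    def test_curve_non_increasing_for_random_dose(self, grid):
        rng = np.random.default_rng(0)
        mask = box_mask(grid, 5000)
        curve = dvh(DoseGrid(rng.random(grid.shape) * 30, grid), mask)
        assert np.all(np.diff(curve.volume_cc) <= 1e-12)

    def test_dmean_consistent_with_curve_integral(self, grid):
        rng = np.random.default_rng(1)
        mask = box_mask(grid, 4000)
        dose = DoseGrid(rng.random(grid.shape) * 20, grid)
        curve = dvh(dose, mask, bin_width_gy=0.1)
        # integral of the cumulative curve over dose = mean dose x volume
        integral = np.trapezoid(curve.volume_cc, curve.edges_gy)
        dmean = dose.values[mask.voxels].mean()
        assert integral / mask.volume_cc == pytest.approx(dmean, abs=0.1)

    def test_empty_mask_rejected(self, grid):
        empty = StructureMask("E", np.zeros(grid.shape, bool), grid)
        with pytest.raises(ValueError):
            dvh(DoseGrid(np.ones(grid.shape), grid), empty)


class TestTg101:
    def test_uniform_low_dose_esophagus_passes(self, grid):
        eso = box_mask(grid, 800, "ESO")
        dose = DoseGrid(np.where(eso.voxels, 10.0, 0.0), grid)
        table = tg101_metrics(dose, {"ESO": eso})
        t = table.set_index(["oar", "metric"])
        assert t.loc[("ESO", "V19.5Gy"), "value"] == 0.0
        assert t.loc[("ESO", "Dmax"), "value"] == 10.0
        assert t.loc[("ESO", "V19.5Gy"), "passed"] and t.loc[("ESO", "Dmax"), "passed"]

    def test_hot_esophagus_fails_dmax(self, grid):
        eso = box_mask(grid, 800, "ESO")
        dose = DoseGrid(np.where(eso.voxels, 40.0, 0.0), grid)
        t = tg101_metrics(dose, {"ESO": eso}).set_index(["oar", "metric"])
        assert not t.loc[("ESO", "Dmax"), "passed"]

    def test_half_hot_heart_volume_metric(self, grid):
        n = int(round(20.0 / VOX))
        hrt = box_mask(grid, n, "HRT")
        vals = np.zeros(grid.shape)
        vals.reshape(-1)[: n // 2] = 40.0
        t = tg101_metrics(DoseGrid(vals, grid), {"HRT": hrt}).set_index(["oar", "metric"])
        assert t.loc[("HRT", "V32Gy"), "value"] == pytest.approx(10.0, abs=VOX)
        assert t.loc[("HRT", "V32Gy"), "passed"]  # < 15 cc

    def test_missing_organ_flagged_not_fatal(self, grid):
        eso = box_mask(grid, 100, "ESO")
        dose = DoseGrid(np.zeros(grid.shape), grid)
        table = tg101_metrics(dose, {"ESO": eso})
        missing = table[table.missing]
        assert set(missing.oar) == {"HRT", "LNG", "SC", "GRT", "TRA"}
        assert not table[table.oar == "ESO"].missing.any()


class TestSignedMinDistance:
    def test_disjoint_spheres_surface_gap(self, grid):
        a = sphere_mask(grid, (0, 0, -2), 1.0)
        b = sphere_mask(grid, (0, 0, 2), 1.0)
        assert signed_min_distance(a, b) == pytest.approx(2.0, abs=0.5)

    def test_overlapping_spheres_penetration_depth(self, grid):
        a = sphere_mask(grid, (0, 0, -0.75), 1.0)
        b = sphere_mask(grid, (0, 0, 0.75), 1.0)
        assert signed_min_distance(a, b) == pytest.approx(-0.5, abs=0.5)
        assert signed_min_distance(a, b) < 0

    def test_identical_masks_negative(self, grid):
        a = sphere_mask(grid, (0, 0, 0), 1.0)
        assert signed_min_distance(a, a) < 0

    def test_symmetric_for_disjoint_masks(self, grid):
        a = sphere_mask(grid, (-1.5, 0, 0), 0.8)
        b = sphere_mask(grid, (2.0, 0.5, 0), 1.0)
        assert signed_min_distance(a, b) == signed_min_distance(b, a)

    def test_empty_mask_rejected(self, grid):
        a = sphere_mask(grid, (0, 0, 0), 1.0)
        empty = StructureMask("E", np.zeros(grid.shape, bool), grid)
        with pytest.raises(ValueError):
            signed_min_distance(a, empty)


class TestRom:
    def test_static_scene_zero_rom(self, grid):
        g = sphere_mask(grid, (0, 0, 0), 1.0)
        o = sphere_mask(grid, (0, 0, 3), 0.8)
        r = rom(g, g, o, o)
        assert r.rom_cm == 0.0

    def test_gtv_approaching_fixed_oar(self, grid):
        # GTV moves 1 cm toward an OAR initially 2 cm away
        g0 = sphere_mask(grid, (0, 0, -3.0), 1.0)
        g4 = sphere_mask(grid, (0, 0, -2.0), 1.0)
        o = sphere_mask(grid, (0, 0, 1.0), 1.0)
        r = rom(g0, g4, o, o)
        assert r.d_inh_cm == pytest.approx(2.0, abs=0.5)
        assert r.d_exh_cm == pytest.approx(1.0, abs=0.5)
        assert r.rom_cm == pytest.approx(1.0, abs=0.5)

    def test_co_moving_pair_zero_rom(self, grid):
        g0 = sphere_mask(grid, (0, 0, -2.0), 1.0)
        o0 = sphere_mask(grid, (0, 0, 1.0), 0.8)
        g4 = sphere_mask(grid, (0, 0, -1.0), 1.0)
        o4 = sphere_mask(grid, (0, 0, 2.0), 0.8)
        assert rom(g0, g4, o0, o4).rom_cm == pytest.approx(0.0, abs=0.5)

    def test_invariant_under_global_translation(self, grid):
        g0 = sphere_mask(grid, (0, 0, -2.0), 1.0)
        g4 = sphere_mask(grid, (0, 0, -1.5), 1.0)
        o0 = sphere_mask(grid, (0, 0, 1.5), 0.8)
        o4 = sphere_mask(grid, (0, 0, 1.0), 0.8)
        base = rom(g0, g4, o0, o4)
        t = np.array([0.5, -0.25, 0.75])
        g0t = sphere_mask(grid, np.array([0, 0, -2.0]) + t, 1.0)
        g4t = sphere_mask(grid, np.array([0, 0, -1.5]) + t, 1.0)
        o0t = sphere_mask(grid, np.array([0, 0, 1.5]) + t, 0.8)
        o4t = sphere_mask(grid, np.array([0, 0, 1.0]) + t, 0.8)
        moved = rom(g0t, g4t, o0t, o4t)
        assert moved.rom_cm == pytest.approx(base.rom_cm, abs=0.5)


def make_records(rom_values, sparing_values, d_inh=1.0):
    return [SparingRecord(f"O{i}", "p", r, d_inh, s)
            for i, (r, s) in enumerate(zip(rom_values, sparing_values))]


class TestSparingRegression:
    def test_known_slope_recovered(self):
        rng = np.random.default_rng(21)
        x = rng.uniform(0.0, 1.5, 30)
        y = 0.02 * x + rng.normal(0, 0.002, 30)
        res = sparing_regression(make_records(x, y))
        assert 0.015 <= res["slope"] <= 0.025
        assert res["p_value"] < 1e-3

    def test_collinear_points_perfect_fit(self):
        x = np.linspace(0.1, 1.0, 10)
        res = sparing_regression(make_records(x, 0.03 * x + 0.01))
        assert res["p_value"] < 1e-20
        assert res["r_squared"] == pytest.approx(1.0, abs=1e-9)

    def test_slope_recovery_bias_small(self):
        # < 10% bias at n = 30 with noise sd = 10% of the slope
        slopes = []
        true = 0.02
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0.0, 1.5, 30)
            y = true * x + rng.normal(0, 0.1 * true, 30)
            slopes.append(sparing_regression(make_records(x, y))["slope"])
        assert abs(np.mean(slopes) - true) <= 0.1 * true

    def test_type_one_error_calibrated(self):
        # slope-0 generative model: rejection rate at alpha=0.05 in [0.02, 0.10]
        rejections = 0
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            x = rng.uniform(0.0, 1.5, 30)
            y = 0.01 + rng.normal(0, 0.005, 30)
            if sparing_regression(make_records(x, y))["p_value"] < 0.05 >= 0:
                rejections += 1
        assert 0.02 <= rejections / 200 <= 0.10

    def test_too_few_or_degenerate_records_rejected(self):
        with pytest.raises(ValueError):
            sparing_regression(make_records([0.5, 0.7], [0.01, 0.02]))
        with pytest.raises(ValueError, match="variance"):
            sparing_regression(make_records([0.5] * 5, np.linspace(0, 0.02, 5)))


class TestProximityProfile:
    def test_far_oars_near_zero_sparing(self):
        recs = make_records([0.1] * 5, [0.001] * 5, d_inh=3.0)
        prof = proximity_profile(recs)
        assert len(prof) == 1
        assert prof.iloc[0]["bin"] == ">= 2"
        assert prof.iloc[0]["mean_sparing"] == pytest.approx(0.001)

    def test_near_bin_exceeds_far_bin(self):
        near = [SparingRecord(f"N{i}", "p", 0.5, 0.5, 0.05) for i in range(4)]
        far = [SparingRecord(f"F{i}", "p", 0.5, 3.0, 0.002) for i in range(4)]
        prof = proximity_profile(near + far).set_index("bin")
        assert prof.loc["[0, 1.5)", "mean_sparing"] > prof.loc[">= 2", "mean_sparing"]

    def test_overlapping_oars_get_own_bin(self):
        recs = (make_records([0.5] * 3, [0.04] * 3, d_inh=-0.3)
                + make_records([0.5] * 3, [0.01] * 3, d_inh=1.0))
        prof = proximity_profile(recs)
        assert "overlap" in set(prof["bin"])

    def test_empty_bins_absent(self):
        recs = make_records([0.5] * 4, [0.01] * 4, d_inh=1.0)
        prof = proximity_profile(recs)
        assert set(prof["bin"]) == {"[0, 1.5)"}


class TestIrradiatedVolume:
    def test_identical_doses_zero_reduction(self, grid):
        body = box_mask(grid, 40000, "BODY")
        vals = np.zeros(grid.shape)
        vals.reshape(-1)[:5000] = 30.0
        d = DoseGrid(vals, grid)
        assert irradiated_volume_reduction(d, d, body, 50.0) == 0.0

    def test_reduction_of_half_the_volume(self, grid):
        body = box_mask(grid, 40000, "BODY")
        a = np.zeros(grid.shape)
        a.reshape(-1)[:4000] = 30.0
        b = np.zeros(grid.shape)
        b.reshape(-1)[:2000] = 30.0
        red = irradiated_volume_reduction(DoseGrid(a, grid), DoseGrid(b, grid), body, 50.0)
        assert red == pytest.approx(50.0)

    def test_zero_itv_volume_rejected(self, grid):
        body = box_mask(grid, 1000, "BODY")
        zero = DoseGrid(np.zeros(grid.shape), grid)
        with pytest.raises(ValueError):
            irradiated_volume_reduction(zero, zero, body, 50.0)
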