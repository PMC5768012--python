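"""Target volumes, BEV apertures and the virtual couch shift."""

import math

import numpy as np
import pytest

from mrl4d.planning import (
    MACHINES,
    Aperture,
    Beam,
    BeamConfig,
    bev_aperture,
    build_itv,
    expand_margin,
    make_plan,
    vcs_shift,
)

from conftest import make_grid, small_entry, sphere_mask


@pytest.fixture(scope="module")
def grid():
    return make_grid(48)


class TestExpandMargin:
    def test_zero_margin_is_identity(self, grid):
        m = sphere_mask(grid, (0, 0, 0), 1.0)
        out = expand_margin(m, 0.0)
        assert np.array_equal(out.voxels, m.voxels)

    def test_sphere_margin_volume_analytic(self, grid):
        # 1 cm sphere + 5 mm margin -> (4/3) pi 1.5^3 = 14.137 cc
        # (generic sub-voxel alignment; exact lattice alignment is degenerate)
        m = sphere_mask(grid, (0.06, 0.1, 0.03), 1.0)
        out = expand_margin(m, 0.5)
        assert out.volume_cc == pytest.approx(4.0 / 3.0 * math.pi * 1.5 ** 3, rel=0.05)

    def test_expansion_contains_input(self, grid):
        m = sphere_mask(grid, (0.3, -0.2, 0.6), 1.2)
        out = expand_margin(m, 0.3)
        assert np.all(out.voxels[m.voxels])

    def test_negative_margin_rejected(self, grid):
        with pytest.raises(ValueError):
            expand_margin(sphere_mask(grid, (0, 0, 0), 1.0), -0.1)


class TestBuildItv:
    def test_static_tumor_itv_is_expanded_gtv(self, grid):
        m = sphere_mask(grid, (0, 0, 0), 1.0)
        itv = build_itv([m] * 8, 0.5)
        assert np.array_equal(itv.voxels, expand_margin(m, 0.5).voxels)

    def test_displaced_spheres_union_matches_lens_formula(self, grid):
        # two 1 cm spheres 1.74 cm apart: V = 2*(4/3)pi - pi(4r+d)(2r-d)^2/12
        r, d = 1.0, 1.74
        a = sphere_mask(grid, (0, 0, -d / 2), r)
        b = sphere_mask(grid, (0, 0, d / 2), r)
        union = build_itv([a] * 4 + [b] * 4, 0.0)
        lens = math.pi * (4 * r + d) * (2 * r - d) ** 2 / 12.0
        expected = 2 * (4.0 / 3.0) * math.pi * r ** 3 - lens
        assert union.volume_cc == pytest.approx(expected, rel=0.05)

    def test_itv_contains_every_phase_gtv(self, toy_phantom):
        gtvs = [toy_phantom.gtv(p) for p in range(8)]
        itv = build_itv(gtvs, 0.5)
        for g in gtvs:
            assert np.all(itv.voxels[g.voxels])

    def test_empty_gtv_rejected(self, grid):
        from mrl4d.core import StructureMask
        empty = StructureMask("GTV", np.zeros(grid.shape, bool), grid)
        with pytest.raises(ValueError):
            build_itv([empty] * 8, 0.5)


class TestBevAperture:
    def test_centered_sphere_traces_projected_circle(self, grid):
        target = sphere_mask(grid, (0, 0, 0), 1.0)
        beam = Beam(0.0, (0, 0, 0))
        ap = bev_aperture(target, beam)
        for k, (lo, hi) in zip(ap.row_indices, ap.openings):
            if np.isnan(lo):
                continue
            v = k * ap.pitch_cm
            if abs(v) >= 1.0:
                continue
            chord = math.sqrt(1.0 - v ** 2)
            assert abs(-lo - chord) <= beam.leaf_width_cm / 2
            assert abs(hi - chord) <= beam.leaf_width_cm / 2

    def test_lateral_displacement_moves_aperture_centroid(self, grid):
        beam = Beam(0.0, (0, 0, 0))  # beam along +y; lateral axis is x
        ap0 = bev_aperture(sphere_mask(grid, (0, 0, 0), 1.0), beam)
        ap1 = bev_aperture(sphere_mask(grid, (1.0, 0, 0), 1.0), beam)
        du = ap1.centroid_cm[0] - ap0.centroid_cm[0]
        assert du == pytest.approx(1.0, abs=0.1)

    def test_leaf_width_changes_area_within_two_rows(self, grid):
        target = sphere_mask(grid, (0, 0, 0), 1.0)
        ap_mrl = bev_aperture(target, Beam(0.0, (0, 0, 0), *MACHINES["mrl"]))
        ap_conv = bev_aperture(target, Beam(0.0, (0, 0, 0), *MACHINES["conventional"]))
        disk = math.pi * 1.0 ** 2
        # both apertures cover at least the projected disk (minus voxel slack)
        assert ap_mrl.area_cm2 >= 0.9 * disk
        assert ap_conv.area_cm2 >= 0.9 * disk
        max_row_area = 2.0 * max(0.72, 0.5) * 2.0  # two rows x max chord width
        assert abs(ap_mrl.area_cm2 - ap_conv.area_cm2) <= max_row_area

    def test_empty_target_rejected(self, grid):
        from mrl4d.core import StructureMask
        empty = StructureMask("T", np.zeros(grid.shape, bool), grid)
        with pytest.raises(ValueError):
            bev_aperture(empty, Beam(0.0, (0, 0, 0)))


class TestVcsShift:
    def test_zero_displacement_is_identity(self, grid):
        ap = bev_aperture(sphere_mask(grid, (0, 0, 0), 1.0), Beam(0.0, (0, 0, 0)))
        out = vcs_shift(ap, (0.0, 0.0, 0.0), Beam(0.0, (0, 0, 0)))
        assert np.array_equal(out.row_indices, ap.row_indices)
        assert np.allclose(out.openings, ap.openings, equal_nan=True)

    def test_cranial_displacement_projects_to_row_axis(self, grid):
        beam = Beam(0.0, (0, 0, 0))
        ap = bev_aperture(sphere_mask(grid, (0, 0, 0), 1.0), beam)
        out = vcs_shift(ap, (0.0, 0.0, 1.0), beam)
        dv = out.centroid_cm[1] - ap.centroid_cm[1]
        assert dv == pytest.approx(1.0, abs=beam.leaf_width_cm / 2)
        assert out.centroid_cm[0] == pytest.approx(ap.centroid_cm[0], abs=1e-9)

    def test_displacement_along_beam_axis_is_invisible(self, grid):
        beam = Beam(0.0, (0, 0, 0))
        ap = bev_aperture(sphere_mask(grid, (0, 0, 0), 1.0), beam)
        out = vcs_shift(ap, (0.0, 3.0, 0.0), beam)
        assert np.allclose(out.openings, ap.openings, equal_nan=True)

    def test_area_preserved_under_shift(self, grid):
        beam = Beam(30.0, (0, 0, 0))
        ap = bev_aperture(sphere_mask(grid, (0, 0, 0), 1.2), beam)
        out = vcs_shift(ap, (0.4, -0.2, 0.9), beam)
        assert out.area_cm2 == pytest.approx(ap.area_cm2, abs=2 * 0.72 * 2.4)


class TestMakePlan:
    def test_static_tumor_tracked_equals_itv_apertures(self, static_phantom):
        bc = BeamConfig(n_beams=3)
        tracked = make_plan(static_phantom, "4dmrl", bc, 50.0, 5)
        itv = make_plan(static_phantom, "itv", bc, 50.0, 5)
        for b in range(3):
            a_itv = itv.aperture(b, 0)
            for p in range(8):
                a_trk = tracked.aperture(b, p)
                assert np.array_equal(a_trk.row_indices, a_itv.row_indices)
                assert np.allclose(a_trk.openings, a_itv.openings, equal_nan=True)

    def test_tracked_apertures_follow_gtv(self, toy_phantom):
        bc = BeamConfig(n_beams=1, angles_deg=(90.0,))
        plan = make_plan(toy_phantom, "4dmrl", bc, 50.0, 5)
        c0 = plan.aperture(0, 0).centroid_cm
        c4 = plan.aperture(0, 4).centroid_cm
        # tumor moves 1 cm cranially between inhale and exhale
        assert c4[1] - c0[1] == pytest.approx(1.0, abs=0.72 / 2)

    def test_tracked_aperture_smaller_than_itv(self, toy_phantom):
        bc = BeamConfig(n_beams=3)
        tracked = make_plan(toy_phantom, "4dmrl", bc, 50.0, 5)
        itv = make_plan(toy_phantom, "itv", bc, 50.0, 5)
        for b in range(3):
            assert tracked.aperture(b, 0).area_cm2 < itv.aperture(b, 0).area_cm2

    def test_aperture_area_constant_across_phases(self, toy_phantom):
        bc = BeamConfig(n_beams=3)
        plan = make_plan(toy_phantom, "4dmrl", bc, 50.0, 5)
        for b in range(3):
            areas = [plan.aperture(b, p).area_cm2 for p in range(8)]
            row_area = 0.72 * (np.nanmax(plan.aperture(b, 0).openings)
                               - np.nanmin(plan.aperture(b, 0).openings))
            assert max(areas) - min(areas) <= 2 * row_area

    def test_prescription_stored_verbatim(self, toy_phantom):
        plan = make_plan(toy_phantom, "4dmrl", BeamConfig(n_beams=1), 52.0, 4)
        assert plan.prescription_gy == 52.0
        assert plan.fractions == 4

    def test_isocenter_constant_across_phases(self, toy_phantom):
        plan = make_plan(toy_phantom, "4dmrl", BeamConfig(n_beams=3), 50.0, 5)
        assert len({b.isocenter_cm for b in plan.beams}) == 1

    def test_machine_presets(self):
        bc = BeamConfig(machine="conventional", n_beams=2)
        assert bc.sad_cm == 100.0 and bc.leaf_width_cm == 0.5
        with pytest.raises(ValueError, match="unknown machine"):
            BeamConfig(machine="cyber")

    def test_unknown_strategy_rejected(self, toy_phantom):
        with pytest.raises(ValueError, match="strategy"):
            make_plan(toy_phantom, "gating", BeamConfig(), 50.0, 5)
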