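"""Geometry: phantoms, margin expansion, axis lengths, NIfTI round trip."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import ndimage

from irisopt.geometry import (
    AxisLengths,
    StructureMask,
    VoxelGrid,
    axis_lengths,
    expand_margin,
    load_mask,
    make_ellipsoid_phantom,
    make_sphere_phantom,
    save_mask,
)

from conftest import unit_grid

TABLE_SEMI_AXES = (28.40, 18.18, 18.18)  # cohort-mean PTV geometry, mm


def effective_radius(volume_mm3: float) -> float:
    return (3.0 * volume_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)


class TestVoxelGrid:
    def test_rejects_bad_spacing_and_dims(self):
        with pytest.raises(ValueError):
            VoxelGrid(spacing=(0.0, 1, 1))
        with pytest.raises(ValueError):
            VoxelGrid(spacing=(1, 1, 1), dims=(0, 4, 4))

    def test_voxel_center_convention(self):
        g = VoxelGrid(spacing=(2, 2, 2), origin=(-4, -4, -4), dims=(4, 4, 4))
        assert g.axis_centers(0)[0] == -3.0  # origin + 0.5*spacing
        assert g.voxel_volume_cm3 == pytest.approx(8.0 / 1000.0)

    def test_same_lattice_detects_fractional_offset(self):
        g = VoxelGrid(spacing=(1, 1, 1), origin=(0, 0, 0), dims=(4, 4, 4))
        shifted = VoxelGrid(spacing=(1, 1, 1), origin=(2, -1, 3), dims=(4, 4, 4))
        off = VoxelGrid(spacing=(1, 1, 1), origin=(0.4, 0, 0), dims=(4, 4, 4))
        assert g.same_lattice(shifted)
        assert not g.same_lattice(off)


class TestSpherePhantom:
    def test_volume_matches_analytic_within_2pct(self):
        s = make_sphere_phantom(unit_grid(17.0), (0, 0, 0), 15.0)
        analytic = 4.0 / 3.0 * math.pi * 15.0**3
        assert s.volume_mm3 == pytest.approx(analytic, rel=0.02)

    def test_tiny_sphere_at_voxel_center_sets_one_voxel(self):
        g = VoxelGrid(spacing=(1, 1, 1), origin=(0, 0, 0), dims=(5, 5, 5))
        s = make_sphere_phantom(g, (2.5, 2.5, 2.5), 0.4)  # a voxel center
        assert s.n_voxels == 1

    def test_refinement_reduces_volume_error(self):
        analytic = 4.0 / 3.0 * math.pi * 15.0**3
        coarse = make_sphere_phantom(unit_grid(17.0, 1.0), (0, 0, 0), 15.0)
        fine = make_sphere_phantom(unit_grid(17.0, 0.5), (0, 0, 0), 15.0)
        assert abs(fine.volume_mm3 - analytic) < abs(coarse.volume_mm3 - analytic)

    def test_sphere_outside_grid_raises(self):
        g = VoxelGrid(spacing=(1, 1, 1), origin=(0, 0, 0), dims=(5, 5, 5))
        with pytest.raises(ValueError, match="empty"):
            make_sphere_phantom(g, (100, 100, 100), 2.0)


class TestEllipsoidPhantom:
    def test_cohort_mean_geometry_axis_lengths(self):
        g = unit_grid(32.0)
        e = make_ellipsoid_phantom(g, (0, 0, 0), TABLE_SEMI_AXES)
        ax = axis_lengths(e)
        assert ax.a_max == pytest.approx(56.80, abs=1.0)  # one voxel spacing
        assert ax.a_min == pytest.approx(36.36, abs=1.0)

    def test_equal_semi_axes_degenerates_to_sphere(self):
        g = unit_grid(12.0)
        e = make_ellipsoid_phantom(g, (0, 0, 0), (10, 10, 10))
        s = make_sphere_phantom(g, (0, 0, 0), 10.0)
        assert np.array_equal(e.mask, s.mask)

    def test_volume_matches_analytic_within_2pct(self):
        e = make_ellipsoid_phantom(unit_grid(32.0), (0, 0, 0), TABLE_SEMI_AXES)
        analytic = 4.0 / 3.0 * math.pi * np.prod(TABLE_SEMI_AXES)
        assert e.volume_mm3 == pytest.approx(analytic, rel=0.02)


class TestExpandMargin:
    def test_zero_margin_is_identity_with_label_promotion(self, sphere10):
        out = expand_margin(sphere10, 0.0)
        assert np.array_equal(out.mask, sphere10.mask)
        assert out.label == "CTV"  # GTV promotes

    def test_negative_margin_rejected(self, sphere10):
        with pytest.raises(ValueError):
            expand_margin(sphere10, -1.0)

    def test_dilated_ball_is_larger_ball_within_one_voxel(self, sphere10):
        out = expand_margin(sphere10, 4.0)
        assert abs(effective_radius(out.volume_mm3) - 14.0) < 1.0

    def test_margin_chain_gtv_ctv_ptv(self, sphere10):
        ctv = expand_margin(sphere10, 2.0)
        ptv = expand_margin(ctv, 4.0)
        assert (ctv.label, ptv.label) == ("CTV", "PTV")
        assert abs(effective_radius(ptv.volume_mm3) - 16.0) < 1.0
        # superset chain
        assert ctv.n_voxels > sphere10.n_voxels
        assert ptv.n_voxels > ctv.n_voxels

    def test_matches_brute_force_distance_oracle(self, rng):
        # random blob: union of a few small balls
        g = unit_grid(10.0)
        mask = np.zeros(g.dims, dtype=bool)
        for _ in range(3):
            c = rng.uniform(-4, 4, size=3)
            s = make_sphere_phantom(g, tuple(c), rng.uniform(2, 4))
            mask |= s.mask
        blob = StructureMask(grid=g, mask=mask)
        out = expand_margin(blob, 2.5)
        pts = blob.voxel_coords_mm()
        centers = np.stack(
            np.meshgrid(*[out.grid.axis_centers(k) for k in range(3)], indexing="ij"), -1
        )
        d2 = ((centers[..., None, :] - pts[None, None, None, :, :]) ** 2).sum(-1)
        oracle = d2.min(axis=-1) <= 2.5**2
        assert np.array_equal(out.mask, oracle)

    @given(m1=st.floats(0, 4), m2=st.floats(0, 4))
    def test_dilation_monotone_in_margin(self, m1, m2):
        s = make_sphere_phantom(unit_grid(8.0), (0, 0, 0), 5.0)
        lo, hi = sorted([m1, m2])
        assert expand_margin(s, lo).n_voxels <= expand_margin(s, hi).n_voxels

    def test_dilation_composition_within_one_voxel(self, sphere10):
        seq = expand_margin(expand_margin(sphere10, 2.0), 4.0)
        direct = expand_margin(sphere10, 6.0)
        r_seq = effective_radius(seq.volume_mm3)
        r_direct = effective_radius(direct.volume_mm3)
        assert abs(r_seq - r_direct) < 1.0


class TestAxisLengths:
    def test_sphere_diameter_30(self):
        s = make_sphere_phantom(unit_grid(17.0), (0, 0, 0), 15.0)
        ax = axis_lengths(s)
        assert ax.a_max == pytest.approx(30.0, abs=1.0)
        assert ax.a_min == pytest.approx(30.0, abs=1.0)

    def test_single_voxel_reports_spacing(self):
        g = VoxelGrid(spacing=(1, 1, 1), origin=(0, 0, 0), dims=(5, 5, 5))
        s = make_sphere_phantom(g, (2.5, 2.5, 2.5), 0.4)
        ax = axis_lengths(s)
        assert (ax.a_max, ax.a_min) == (1.0, 1.0)

    def test_translation_invariance(self):
        g = unit_grid(40.0)
        a = make_ellipsoid_phantom(g, (0, 0, 0), (20, 12, 12))
        b = make_ellipsoid_phantom(g, (7, -5, 3), (20, 12, 12))
        ax_a, ax_b = axis_lengths(a), axis_lengths(b)
        assert ax_a.a_max == pytest.approx(ax_b.a_max, abs=1.0)
        assert ax_a.a_min == pytest.approx(ax_b.a_min, abs=1.0)

    def test_feret_matches_brute_force_pairwise_oracle(self, rng):
        g = unit_grid(10.0)
        mask = np.zeros(g.dims, dtype=bool)
        for _ in range(3):
            c = rng.uniform(-5, 5, size=3)
            mask |= make_sphere_phantom(g, tuple(c), rng.uniform(2, 4)).mask
        blob = StructureMask(grid=g, mask=mask)
        surface = blob.mask & ~ndimage.binary_erosion(blob.mask)
        pts = np.argwhere(surface) + 0.5 + np.asarray(g.origin)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        assert axis_lengths(blob).a_max == pytest.approx(d.max() + 1.0, abs=1e-9)

    def test_refinement_converges(self):
        coarse = make_ellipsoid_phantom(unit_grid(32.0, 2.0), (0, 0, 0), TABLE_SEMI_AXES)
        fine = make_ellipsoid_phantom(unit_grid(32.0, 1.0), (0, 0, 0), TABLE_SEMI_AXES)
        assert abs(axis_lengths(fine).a_max - axis_lengths(coarse).a_max) < 2.0
        assert abs(fine.volume_mm3 - coarse.volume_mm3) < coarse.volume_mm3 * 0.05

    def test_invariants_of_type(self):
        with pytest.raises(ValueError):
            AxisLengths(a_max=10.0, a_min=12.0)
        with pytest.raises(ValueError):
            AxisLengths(a_max=5.0, a_min=0.0)

    def test_empty_mask_raises(self):
        g = VoxelGrid(spacing=(1, 1, 1), dims=(3, 3, 3))
        s = StructureMask(grid=g, mask=np.zeros((3, 3, 3), dtype=bool))
        with pytest.raises(ValueError):
            axis_lengths(s)


class TestNiftiIO:
    def test_round_trip_preserves_grid_and_mask(self, sphere10, tmp_path):
        path = str(tmp_path / "mask.nii.gz")
        save_mask(sphere10, path)
        back = load_mask(path, label="GTV")
        assert np.array_equal(back.mask, sphere10.mask)
        assert np.allclose(back.grid.spacing, sphere10.grid.spacing)
        assert np.allclose(back.grid.origin, sphere10.grid.origin)
        assert back.label == "GTV"
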