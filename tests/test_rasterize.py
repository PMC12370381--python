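"""Slab-model rasterization, volume oracles and reslicing."""

import numpy as np
import pytest

from srsqa import (
    PlanarContour,
    Sphere,
    StructureSet,
    SupersamplingScheme,
    VoxelGrid,
    mc_volume_oracle,
    rasterize_structure,
    reslice_structure,
    structure_volume,
)
from conftest import CT_SPACING, sphere_grid


def square_contour(z, half=5.0, center=(0.0, 0.0)):
    v = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float) * half
    return PlanarContour(z=z, vertices=v + np.asarray(center))


class TestRasterize:
    def test_single_slice_square_volume_is_slab_volume(self):
        # 10x10 mm square on one slice, ST = 1 mm, half-slab end caps -> 0.1 cm³
        # pixel centres at -8.25 + 0.5k and sub-pixel pitch 0.1 mm put the
        # sample points symmetrically about the square's edges at ±5, so the
        # in-plane fraction is exact
        grid = VoxelGrid.from_extent((-8.25, -8.25, -2), (8, 8, 2), (0.5, 0.5, 1.0))
        res = structure_volume([square_contour(0.0)], grid, SupersamplingScheme((5, 5, 4)))
        assert res.volume_cm3 == pytest.approx(0.100, rel=1e-6)

    def test_volume_equals_occupancy_sum(self):
        sph = Sphere(center=(0.3, 0.2, 0.4), R=5.0)
        grid = sphere_grid(sph.center, sph.R)
        contours = [c for z in grid.slice_positions for c in sph.contours_at(float(z))]
        occ = rasterize_structure(contours, grid)
        vol = structure_volume(contours, grid).volume_cm3
        assert vol == pytest.approx(occ.sum() * grid.voxel_volume_mm3 / 1000.0, rel=1e-12)

    def test_sphere_volume_within_3se_of_monte_carlo_oracle(self):
        sph = Sphere(center=(0.31, 0.17, 0.63), R=3.5)
        grid = sphere_grid(sph.center, sph.R)
        contours = [c for z in grid.slice_positions for c in sph.contours_at(float(z))]
        vol = structure_volume(contours, grid).volume_cm3

        # oracle measures the same slab-model solid: in-plane containment
        # against the slab's circle cross-section
        zs = np.array(sorted({c.z for c in contours}))
        radii = {c.z: np.hypot(*(c.vertices - np.array(sph.center[:2])).T).mean() for c in contours}

        def inside(pts):
            out = np.zeros(len(pts), dtype=bool)
            for z in zs:
                sel = (pts[:, 2] >= z - 0.5) & (pts[:, 2] < z + 0.5)
                rr = np.hypot(pts[sel, 0] - sph.center[0], pts[sel, 1] - sph.center[1])
                out[sel] = rr <= radii[z]
            return out

        lo, hi = sph.bbox(margin=1.0)
        mc = mc_volume_oracle(inside, (lo, hi), n=10**6, seed=1)
        assert abs(vol - mc.volume_cm3) < 3 * mc.standard_error_cm3

    def test_translation_equivariance(self):
        sph = Sphere(center=(0.0, 0.0, 0.3), R=4.0)
        grid = sphere_grid(sph.center, sph.R)
        contours = [c for z in grid.slice_positions for c in sph.contours_at(float(z))]
        v0 = structure_volume(contours, grid).volume_cm3
        shift = np.array([7.2, -3.6, 4.0])  # multiple of the voxel spacing
        grid2 = VoxelGrid(tuple(np.add(grid.origin, shift)), grid.spacing, grid.dims)
        moved = [PlanarContour(z=c.z + shift[2], vertices=c.vertices + shift[:2]) for c in contours]
        v1 = structure_volume(moved, grid2).volume_cm3
        assert v1 == pytest.approx(v0, rel=1e-12)

    def test_supersampling_convergence_for_7mm_sphere(self):
        sph = Sphere(center=(0.21, 0.44, 0.35), R=3.5)
        grid = sphere_grid(sph.center, sph.R)
        contours = [c for z in grid.slice_positions for c in sph.contours_at(float(z))]
        v_lo = structure_volume(contours, grid, SupersamplingScheme((3, 3, 4))).volume_cm3
        v_hi = structure_volume(contours, grid, SupersamplingScheme((6, 6, 8))).volume_cm3
        assert abs(v_hi - v_lo) / v_hi < 0.005

    def test_monotone_coverage_adding_a_contour(self):
        grid = VoxelGrid.from_extent((-8, -8, -4), (8, 8, 4), (0.5, 0.5, 1.0))
        partial = [square_contour(0.0)]
        extended = [square_contour(0.0), square_contour(1.0, half=3.0)]
        v0 = structure_volume(partial, grid).volume_cm3
        v1 = structure_volume(extended, grid).volume_cm3
        assert v1 >= v0

    def test_contour_outside_grid_is_an_error_naming_the_structure(self):
        grid = VoxelGrid.from_extent((-8, -8, 0), (8, 8, 2), (0.5, 0.5, 1.0))
        with pytest.raises(ValueError, match="box"):
            rasterize_structure([square_contour(9.0)], grid, name="box")

    def test_empty_structure_is_an_error(self):
        grid = VoxelGrid.from_extent((-8, -8, 0), (8, 8, 2), (0.5, 0.5, 1.0))
        with pytest.raises(ValueError):
            structure_volume([], grid)


class TestReslice:
    def _sphere_set(self, R=10.0, center=(0.3, 0.3, 0.5)):
        sph = Sphere(center=center, R=R)
        grid = sphere_grid(center, R)
        ss = StructureSet()
        for z in grid.slice_positions:
            for c in sph.contours_at(float(z)):
                ss.add("t", c)
        return sph, grid, ss

    def test_identity_reslice_keeps_contour_planes(self):
        sph, grid, ss = self._sphere_set()
        out = reslice_structure(ss, new_st=1.0, origin=grid.origin, shapes={"t": sph})
        np.testing.assert_allclose(out.z_planes("t"), ss.z_planes("t"))

    def test_coarser_reslice_volume_within_5pct_of_closed_form(self):
        sph, grid, ss = self._sphere_set(R=10.0)
        out = reslice_structure(ss, new_st=2.0, origin=grid.origin, shapes={"t": sph})
        grid2 = VoxelGrid(grid.origin, (0.6, 0.6, 2.0), (grid.dims[0], grid.dims[1], grid.dims[2] // 2))
        v = structure_volume(out["t"], grid2, slab_thickness=2.0).volume_cm3
        assert abs(v / sph.volume_cm3 - 1.0) < 0.05

    def test_small_sphere_between_slices_keeps_nonzero_volume(self):
        # 3-mm sphere centred between 2-mm slices: end-capping keeps volume > 0
        sph = Sphere(center=(0.0, 0.0, 1.0), R=1.5)
        grid = VoxelGrid.from_extent((-4, -4, -4), (4, 4, 6), (0.6, 0.6, 2.0))
        contours = [c for z in grid.slice_positions for c in sph.contours_at(float(z))]
        assert contours, "slices at z=0 and z=2 intersect the sphere"
        v = structure_volume(contours, grid, slab_thickness=2.0).volume_cm3
        assert v > 0

    def test_polygon_reslice_takes_nearest_plane(self):
        ss = StructureSet()
        ss.add("t", square_contour(0.0, half=5.0))
        ss.add("t", square_contour(1.0, half=3.0))
        out = reslice_structure(ss, new_st=2.0, origin=(0.0, 0.0, 0.0))
        # new plane at z=0 takes the z=0 contour; z=2 takes nearest (z=1)
        planes = out.grouped_by_plane("t")
        assert set(planes) == {-2.0, 0.0, 2.0}
        assert planes[2.0][0].vertices[:, 0].max() == pytest.approx(3.0)

    def test_reslice_far_structure_warns_empty(self):
        ss = StructureSet()
        ss.add("t", square_contour(0.0))
        with pytest.warns(UserWarning, match="empty"):
            out = reslice_structure(ss, new_st=0.25, origin=(0, 0, 100.0), shapes={"t": Sphere(center=(0, 0, 200.0), R=0.1)})
        assert out["t"] == []


class TestMonteCarloOracle:
    def test_everywhere_inside_gives_box_volume(self):
        res = mc_volume_oracle(lambda p: np.ones(len(p), bool), ((0, 0, 0), (10, 10, 10)), 10**4, seed=0)
        assert res.volume_cm3 == pytest.approx(1.0)
        assert res.standard_error_cm3 == 0.0

    def test_sphere_closed_form_within_3se(self):
        sph = Sphere(center=(0, 0, 0), R=5.0)
        res = mc_volume_oracle(sph.contains, ((-6, -6, -6), (6, 6, 6)), 10**6, seed=1)
        assert abs(res.volume_cm3 - sph.volume_cm3) < 3 * res.standard_error_cm3

    def test_half_space_is_half_the_box(self):
        res = mc_volume_oracle(lambda p: p[:, 0] <= 5.0, ((0, 0, 0), (10, 10, 10)), 10**6, seed=2)
        assert abs(res.volume_cm3 - 0.5) < 3 * res.standard_error_cm3

    def test_zero_measure_box_rejected(self):
        with pytest.raises(ValueError):
            mc_volume_oracle(lambda p: np.ones(len(p), bool), ((0, 0, 0), (0, 1, 1)), 10**4, seed=0)

    def test_seed_reproducibility(self):
        f = lambda p: (p**2).sum(axis=1) <= 16.0
        a = mc_volume_oracle(f, ((-5, -5, -5), (5, 5, 5)), 10**5, seed=9)
        b = mc_volume_oracle(f, ((-5, -5, -5), (5, 5, 5)), 10**5, seed=9)
        assert a.volume_cm3 == b.volume_cm3
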