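"""DVH curves, isodose volumes and SRS plan-quality indices."""

import numpy as np
import pytest

from srsqa import (
    DoseGrid,
    DoseModelParams,
    Sphere,
    VoxelGrid,
    analytic_isodose_volume,
    conformity_index,
    cumulative_dvh,
    d95,
    gradient_index,
    isodose_volume,
    radial_dose,
    trilinear_dose,
    v_at_dose,
)
from srsqa.dvh import DVHCurve
from srsqa.regions import SphereRegion
from conftest import sphere_grid


def uniform_dose(pct, prescription=30.0, n=12, spacing=1.0):
    grid = VoxelGrid((0, 0, 0), (spacing,) * 3, (n, n, n))
    values = np.full((n, n, n), pct / 100.0 * prescription)
    return DoseGrid(grid, values, prescription)


def square_structure(z_list, half=4.0):
    from srsqa import PlanarContour

    v = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], float) * half + 5.5
    return [PlanarContour(z=z, vertices=v) for z in z_list]


class TestTrilinearDose:
    def test_voxel_centre_identity(self):
        dose = uniform_dose(100.0)
        dose.values[2, 3, 4] = 0.6 * 30.0
        assert trilinear_dose(dose, (2.0, 3.0, 4.0)) == pytest.approx(60.0)

    def test_midpoint_linearity(self):
        dose = uniform_dose(0.0)
        dose.values[:, :, :] = 0.0
        dose.values[1, 1, 1] = 0.4 * 30.0
        dose.values[2, 1, 1] = 0.6 * 30.0
        assert trilinear_dose(dose, (1.5, 1.0, 1.0)) == pytest.approx(50.0)

    def test_constant_grid_everywhere(self):
        dose = uniform_dose(73.0)
        rng = np.random.default_rng(0)
        pts = rng.uniform(0.0, 11.0, size=(100, 3))
        np.testing.assert_allclose(trilinear_dose(dose, pts), 73.0, rtol=1e-12)

    def test_out_of_hull_lookup_is_clamped_with_warning(self):
        dose = uniform_dose(50.0)
        with pytest.warns(UserWarning, match="clamped"):
            assert trilinear_dose(dose, (-5.0, 0.0, 0.0)) == pytest.approx(50.0)


class TestDVHCurve:
    def test_uniform_dose_curve_is_a_step_at_the_dose(self):
        dose = uniform_dose(100.0)
        curve = cumulative_dvh(square_structure([4.0, 5.0, 6.0]), dose, dose.grid)
        assert v_at_dose(curve, 100.0) == pytest.approx(100.0)
        assert v_at_dose(curve, 100.3) == pytest.approx(0.0)
        assert curve.total_cm3 == pytest.approx(8 * 8 * 3 / 1000.0, rel=1e-6)

    def test_two_level_dose_gives_single_half_step(self):
        dose = uniform_dose(50.0)
        dose.values[:, :, 6:] = 1.5 * 30.0  # upper half at 150%
        curve = cumulative_dvh(
            square_structure([4.0, 5.0, 6.0, 7.0]), dose, dose.grid, interpolation="nearest"
        )
        assert v_at_dose(curve, 100.0) == pytest.approx(50.0, abs=1.0)
        assert v_at_dose(curve, 40.0) == pytest.approx(100.0)
        assert v_at_dose(curve, 160.0) == pytest.approx(0.0)

    def test_monotone_and_normalised(self, clinical_case):
        t = clinical_case.targets[0]
        dose = clinical_case.dose_window(t)
        curve = cumulative_dvh(clinical_case.structures[t.name], dose, clinical_case.ct_grid)
        assert np.all(np.diff(curve.volume_cm3) <= 1e-12)
        assert curve.volume_pct[0] == pytest.approx(100.0)

    def test_zero_volume_structure_rejected(self):
        dose = uniform_dose(100.0)
        with pytest.raises(ValueError):
            cumulative_dvh([], dose, dose.grid)


class TestD95AndVAtDose:
    def test_uniform_dose_d95_equals_the_dose(self):
        dose = uniform_dose(103.39)
        curve = cumulative_dvh(square_structure([5.0]), dose, dose.grid)
        assert d95(curve) == pytest.approx(103.39, abs=0.1)

    def test_step_curve_d95_is_the_step_dose(self):
        # 96% of the volume at >= 101%: D95 = 101
        edges = np.arange(0.0, 120.0, 0.1)
        vol = np.where(edges <= 101.0, 1.0, 0.04)
        vol[edges > 110.0] = 0.0
        curve = DVHCurve(edges=edges, volume_cm3=vol)
        assert d95(curve) == pytest.approx(101.0, abs=0.11)

    def test_consistency_v_at_d95(self, clinical_case):
        t = clinical_case.targets[0]
        dose = clinical_case.dose_window(t)
        curve = cumulative_dvh(clinical_case.structures[t.name], dose, clinical_case.ct_grid)
        assert v_at_dose(curve, d95(curve)) >= 95.0 - 0.1


class TestIndices:
    @pytest.mark.parametrize(
        "tv,piv,tvpiv,expected", [(1, 1, 1, 1.0), (1, 2, 1, 0.5), (2, 2, 1, 0.25)]
    )
    def test_paddick_examples(self, tv, piv, tvpiv, expected):
        assert conformity_index(tv, piv, tvpiv) == pytest.approx(expected)

    def test_paddick_scale_invariance(self):
        assert conformity_index(3.3, 4.1, 2.9) == pytest.approx(
            conformity_index(33.0, 41.0, 29.0)
        )

    def test_paddick_inconsistent_volumes_rejected(self):
        with pytest.raises(ValueError):
            conformity_index(1.0, 1.0, 1.5)

    def test_gradient_index_examples(self):
        assert gradient_index(2.0, 1.0) == pytest.approx(2.0)
        assert gradient_index(1.0, 1.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            gradient_index(1.0, 0.0)


@pytest.fixture(scope="module")
def sphere_phantom():
    params = DoseModelParams(R=3.0, g=3.0)
    center = np.array([0.23, 0.41, 0.37])

    def model(pts):
        return radial_dose(np.linalg.norm(pts - center, axis=-1), params)

    r25 = 3.0 + 2 * 3.0 * np.log2(2.0)  # 25% radius = R + 2g
    ct = sphere_grid(center, r25 + 2.0)
    dg = VoxelGrid.from_extent(
        tuple(center - r25 - 4), tuple(center + r25 + 4), (0.5, 0.5, 0.5),
        lattice_origin=(0.25, 0.25, 0.25),
    )
    dose = DoseGrid.from_model(model, dg, 30.0)
    region = SphereRegion(tuple(center), r25)
    return params, dose, region, ct


class TestIsodoseVolume:

    def test_fine_grid_v50_within_1pct_of_closed_form(self, sphere_phantom):
        params, dose, region, ct = sphere_phantom
        v50 = isodose_volume(dose, 50.0, region, ct)
        assert abs(v50 / analytic_isodose_volume(50.0, params) - 1.0) < 0.01

    def test_gi_closed_form_within_2pct(self, sphere_phantom):
        # R = 3, g = 3: GI = ((R+g)/R)³ = 8
        params, dose, region, ct = sphere_phantom
        v = isodose_volume(dose, (100.0, 50.0), region, ct)
        assert gradient_index(v[50.0], v[100.0]) == pytest.approx(8.0, rel=0.02)

    def test_level_above_grid_maximum_is_zero(self, sphere_phantom):
        _, dose, region, ct = sphere_phantom
        assert isodose_volume(dose, 500.0, region, ct) == 0.0

    def test_nestedness_in_level(self, sphere_phantom):
        _, dose, region, ct = sphere_phantom
        v = isodose_volume(dose, (50.0, 80.0, 100.0), region, ct)
        assert v[50.0] >= v[80.0] >= v[100.0]

    def test_dg_convergence_toward_closed_form(self):
        # |error| decreases monotonically through DG = 2, 1, 0.5 mm
        params = DoseModelParams(R=3.0, g=3.0)
        center = np.array([0.13, 0.29, 0.41])

        def model(pts):
            return radial_dose(np.linalg.norm(pts - center, axis=-1), params)

        r25 = 9.0
        ct = sphere_grid(center, r25 + 2.0)
        region = SphereRegion(tuple(center), r25)
        errs = []
        for dg_mm in (2.0, 1.0, 0.5):
            dg = VoxelGrid.from_extent(
                tuple(center - r25 - 5), tuple(center + r25 + 5), (dg_mm,) * 3,
                lattice_origin=(0.25, 0.25, 0.25),
            )
            dose = DoseGrid.from_model(model, dg, 30.0)
            v = isodose_volume(dose, 100.0, region, ct)
            errs.append(abs(v / analytic_isodose_volume(100.0, params) - 1.0))
        assert errs[0] > errs[1] > errs[2]

    def test_dvh_and_isodose_volume_agree_within_a_bin(self, sphere_phantom):
        params, dose, region, ct = sphere_phantom
        sph = Sphere(center=region.center, R=params.R)
        contours = [c for z in ct.slice_positions for c in sph.contours_at(float(z))]
        curve = cumulative_dvh(contours, dose, ct)
        v80_dvh = v_at_dose(curve, 80.0) / 100.0 * curve.total_cm3
        from srsqa.regions import StructureRegion

        v80_direct = isodose_volume(dose, 80.0, StructureRegion(contours), ct)
        assert v80_dvh == pytest.approx(v80_direct, rel=1e-6)
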