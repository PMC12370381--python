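import numpy as np
import pytest

from srsqa import (
    ClinicalCaseSpec,
    PlanarContour,
    VoxelGrid,
    make_clinical_like_case,
    make_ground_truth_bundle,
)

CT_SPACING = (0.6, 0.6, 1.0)


@pytest.fixture(scope="session")
def unit_square():
    return PlanarContour(z=0.0, vertices=np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float))


@pytest.fixture(scope="session")
def small_gt_bundle():
    """A reduced ground-truth bundle (8 spheres per diameter) for unit tests."""
    return make_ground_truth_bundle(
        diameters=(3.0, 7.0, 10.0), n_per_diameter=8, ct_spacing=CT_SPACING, seed=42
    )


@pytest.fixture(scope="session")
def clinical_case():
    """One deterministic two-lesion clinical-like case."""
    spec = ClinicalCaseSpec(diameters_mm=(10.0, 20.0), seed=7)
    return make_clinical_like_case(spec)


def sphere_grid(center, radius, spacing=CT_SPACING, margin=2.0, lattice_origin=(0.0, 0.0, 0.0)):
    c = np.asarray(center, dtype=float)
    return VoxelGrid.from_extent(
        tuple(c - radius - margin),
        tuple(c + radius + margin),
        spacing,
        lattice_origin=lattice_origin,
    )
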