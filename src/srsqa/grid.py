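"""Regular voxel lattices shared by CT images and dose matrices.

All coordinates are millimetres in the patient (DICOM) frame, axis order
``(x, y, z)``.  A :class:`VoxelGrid` stores geometry only — the origin is the
*centre* of the first voxel, matching the DICOM Image Position (Patient)
convention — so large virtual lattices can be described without allocating
voxel arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VoxelGrid"]


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a regular 3-D lattice.

    Parameters
    ----------
    origin : tuple of float
        Position (mm) of the centre of voxel ``(0, 0, 0)``.
    spacing : tuple of float
        Voxel pitch (mm) along x, y, z; the z component is the slice
        thickness (ST) for a CT lattice or the grid size (DG) for a dose
        lattice.  Strictly positive.
    dims : tuple of int
        Number of voxels along each axis.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.dims) != 3:
            raise ValueError("origin, spacing and dims must each have 3 entries")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if any(int(d) != d or d < 1 for d in self.dims):
            raise ValueError(f"dims must be positive integers, got {self.dims}")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "dims", tuple(int(v) for v in self.dims))

    # -- derived geometry ---------------------------------------------------

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates (mm) along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    @property
    def slice_positions(self) -> np.ndarray:
        """z positions of the slices, ``origin.z + k * ST``."""
        return self.axis_centers(2)

    def extent(self, axis: int) -> tuple[float, float]:
        """Outer edges (mm) of the lattice along one axis (voxel faces)."""
        lo = self.origin[axis] - 0.5 * self.spacing[axis]
        hi = lo + self.spacing[axis] * self.dims[axis]
        return (lo, hi)

    def same_origin(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        """Whether two lattices share a common origin (Image Position Patient)."""
        return all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_extent(
        cls,
        lo: tuple[float, float, float],
        hi: tuple[float, float, float],
        spacing: tuple[float, float, float],
        lattice_origin: tuple[float, float, float] | None = None,
    ) -> "VoxelGrid":
        """Smallest grid covering ``[lo, hi]`` with the given spacing.

        If ``lattice_origin`` is given, voxel centres are constrained to the
        infinite lattice ``lattice_origin + k * spacing`` so that grids built
        around different targets stay mutually aligned (common origin).
        """
        if lattice_origin is None:
            lattice_origin = lo
        origin = []
        dims = []
        for ax in range(3):
            s = spacing[ax]
            k0 = int(np.floor((lo[ax] - lattice_origin[ax]) / s))
            k1 = int(np.ceil((hi[ax] - lattice_origin[ax]) / s))
            origin.append(lattice_origin[ax] + k0 * s)
            dims.append(max(k1 - k0 + 1, 1))
        return cls(tuple(origin), tuple(spacing), tuple(dims))
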