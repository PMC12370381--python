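"""Dose matrices on voxel lattices and continuous dose lookup.

Dose values live at voxel centres.  Continuous lookup supports three
reconstructions of the sampled dose field:

* ``nearest`` — the voxel's own value (no interpolation);
* ``linear`` — trilinear interpolation of the 8 surrounding voxel centres;
* ``cubic`` — tricubic B-spline interpolation (the default for mini-voxel
  isodose sampling).

Trilinear reconstruction systematically erodes small convex isodose
surfaces: the reconstructed level set of a field with surface curvature
``κ`` is displaced inward by about ``κ h² / 8`` for grid spacing ``h``,
which for a 1.5-mm-radius 100% isodose on a 1-mm grid is a ~17% volume
deficit.  The tricubic spline reproduces the local curvature and removes
this bias, which is why it is the default reconstruction for volume
measurements; ``linear`` and ``nearest`` remain available for sensitivity
checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import VoxelGrid

__all__ = ["DoseGrid", "trilinear_dose"]

_ORDERS = {"nearest": 0, "linear": 1, "cubic": 3}


@dataclass
class DoseGrid:
    """Scalar dose values (Gy) on a voxel lattice plus the prescription dose.

    The lattice spacing is the dose-grid size (DG).  All index computations
    normalise to the prescription: 100% = ``prescription_gy``.
    """

    grid: VoxelGrid
    values: np.ndarray
    prescription_gy: float
    _spline_coef: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.dims):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid dims {self.grid.dims}"
            )
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be > 0")

    @classmethod
    def from_model(
        cls,
        model,
        grid: VoxelGrid,
        prescription_gy: float,
        chunk: int = 4_000_000,
    ) -> "DoseGrid":
        """Sample an analytic dose model (returning % of prescription) at the
        voxel centres of ``grid``.  This is the synthetic analogue of a TPS
        recalculation at a given dose-grid size."""
        xs, ys, zs = (grid.axis_centers(a) for a in range(3))
        nx, ny, nz = grid.dims
        vals = np.empty(grid.dims, dtype=float)
        layers = max(1, int(chunk // max(nx * ny, 1)))
        for z0 in range(0, nz, layers):
            z1 = min(z0 + layers, nz)
            X, Y, Z = np.meshgrid(xs, ys, zs[z0:z1], indexing="ij")
            pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
            vals[:, :, z0:z1] = (model(pts) / 100.0 * prescription_gy).reshape(X.shape)
        return cls(grid, vals, prescription_gy)

    def _coefficients(self, order: int) -> np.ndarray:
        if order <= 1:
            return self.values
        if order not in self._spline_coef:
            if min(self.grid.dims) <= order:
                raise ValueError("dose grid too small for spline interpolation")
            self._spline_coef[order] = ndimage.spline_filter(
                self.values, order=order, mode="nearest"
            )
        return self._spline_coef[order]

    def pct_at(
        self, pts: np.ndarray, interpolation: str = "linear", warn_clamped: bool = True
    ) -> np.ndarray:
        """Dose (% of prescription) at arbitrary points (mm).

        Points outside the voxel-centre hull are clamped to the nearest
        in-hull position and flagged with a warning.
        """
        order = _ORDERS[interpolation]
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        coords = np.empty((3, len(pts)))
        n_out = 0
        for a in range(3):
            c = (pts[:, a] - self.grid.origin[a]) / self.grid.spacing[a]
            hi = self.grid.dims[a] - 1
            n_out = max(n_out, int(((c < 0) | (c > hi)).sum()))
            coords[a] = np.clip(c, 0, hi)
        if n_out and warn_clamped:
            warnings.warn(f"{n_out} dose lookup(s) outside the grid hull were clamped")
        vals = ndimage.map_coordinates(
            self._coefficients(order), coords, order=order, prefilter=False, mode="nearest"
        )
        return 100.0 * vals / self.prescription_gy


def trilinear_dose(dose: DoseGrid, p) -> float | np.ndarray:
    """Trilinear interpolation of the 8 surrounding voxel-centre values,
    normalised to the prescription (%).  Scalar in, scalar out."""
    p = np.asarray(p, dtype=float)
    scalar = p.ndim == 1
    out = dose.pct_at(p, interpolation="linear")
    return float(out[0]) if scalar else out
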