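"""Cumulative DVHs, isodose volumes and SRS plan-quality indices.

All quantities are measured by mini-voxel sampling: CT voxels inside (a
window around) the evaluation region are subdivided into mini-voxels, the
dose is reconstructed at each mini-voxel centre from the dose grid (tricubic
B-spline by default; trilinear and nearest-voxel are selectable — see
``srsqa.dose`` for why the spline is the default), and volumes are counts of
mini-voxels times the mini-voxel volume.  Dose thresholds are inclusive
(dose >= level), and "receiving dose greater than the prescribed dose"
(V30Gy) is implemented as >= 100% so that it coincides with the 100% isodose
volume semantics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contours import PlanarContour
from .dose import DoseGrid
from .grid import VoxelGrid
from .rasterize import SupersamplingScheme
from .regions import StructureRegion

__all__ = [
    "DVHCurve",
    "PlanIndices",
    "isodose_volume",
    "cumulative_dvh",
    "d95",
    "v_at_dose",
    "conformity_index",
    "gradient_index",
    "plan_indices",
]

DEFAULT_LEVELS = (110.0, 100.0, 98.0, 95.0, 80.0, 50.0)


# ---------------------------------------------------------------------------
# mini-voxel sampling core


def _mini_dose_samples(
    dose: DoseGrid,
    region,
    ct_grid: VoxelGrid,
    scheme: SupersamplingScheme | None = None,
    chunk: int = 4_000_000,
    collect: bool = True,
    levels: tuple[float, ...] = (),
    interpolation: str = "cubic",
):
    """Iterate mini-voxel centres of the CT window covering ``region``.

    Returns ``(mini_volume_mm3, n_inside, level_counts, values)`` where
    ``values`` concatenates the dose (%) at in-region minis when ``collect``
    and ``level_counts[i]`` counts in-region minis with dose >= levels[i].
    """
    if scheme is None:
        scheme = SupersamplingScheme.for_dose(ct_grid.spacing, dose.grid.spacing)
    lo, hi = region.bbox()
    glo = [ct_grid.extent(a)[0] for a in range(3)]
    ghi = [ct_grid.extent(a)[1] for a in range(3)]
    lo = tuple(max(lo[a], glo[a]) for a in range(3))
    hi = tuple(min(hi[a], ghi[a]) for a in range(3))
    if any(lo[a] >= hi[a] for a in range(3)):
        raise ValueError("evaluation region does not overlap the CT grid")
    window = VoxelGrid.from_extent(lo, hi, ct_grid.spacing, lattice_origin=ct_grid.origin)

    fx, fy, fz = scheme.factors
    mini_vol = ct_grid.voxel_volume_mm3 / (fx * fy * fz)
    mx = (window.axis_centers(0)[:, None] + scheme.offsets(0, ct_grid.spacing[0])[None, :]).ravel()
    my = (window.axis_centers(1)[:, None] + scheme.offsets(1, ct_grid.spacing[1])[None, :]).ravel()
    mz = (window.axis_centers(2)[:, None] + scheme.offsets(2, ct_grid.spacing[2])[None, :]).ravel()

    n_xy = len(mx) * len(my)
    layers = max(1, int(chunk // max(n_xy, 1)))
    n_inside = 0
    counts = np.zeros(len(levels), dtype=np.int64)
    values: list[np.ndarray] = []
    for z0 in range(0, len(mz), layers):
        zblk = mz[z0 : z0 + layers]
        X, Y, Z = np.meshgrid(mx, my, zblk, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        mask = region.contains(pts)
        if not mask.any():
            continue
        sel = pts[mask]
        vals = dose.pct_at(sel, interpolation=interpolation, warn_clamped=False)
        n_inside += int(mask.sum())
        for i, lev in enumerate(levels):
            counts[i] += int((vals >= lev).sum())
        if collect:
            values.append(vals)
    all_vals = np.concatenate(values) if (collect and values) else np.empty(0)
    return mini_vol, n_inside, counts, all_vals


def isodose_volume(
    dose: DoseGrid,
    level: float | tuple[float, ...],
    region,
    ct_grid: VoxelGrid,
    scheme: SupersamplingScheme | None = None,
    interpolation: str = "cubic",
) -> float | dict[float, float]:
    """Volume (cm³) of the region where interpolated dose >= level (%).

    ``level`` may be a single threshold or a tuple; a tuple returns a dict
    and shares one sampling pass.  Deterministic given the scheme.
    """
    levels = (level,) if np.isscalar(level) else tuple(level)
    if any(l <= 0 for l in levels):
        raise ValueError("isodose levels must be > 0")
    mini_vol, n_in, counts, _ = _mini_dose_samples(
        dose, region, ct_grid, scheme, collect=False, levels=levels, interpolation=interpolation
    )
    if n_in == 0:
        raise ValueError("evaluation region contains no sample points")
    vols = {lev: float(c) * mini_vol / 1000.0 for lev, c in zip(levels, counts)}
    return vols[level] if np.isscalar(level) else vols


# ---------------------------------------------------------------------------
# DVH curves


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume curve.

    ``edges`` are dose bin edges in % of prescription; ``volume_cm3[i]`` is
    the structure volume receiving at least ``edges[i]``.  The curve is
    non-increasing and starts at the structure volume.
    """

    edges: np.ndarray
    volume_cm3: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        v = np.asarray(self.volume_cm3, dtype=float)
        if e.shape != v.shape or e.ndim != 1:
            raise ValueError("edges and volumes must be matching 1-D arrays")
        if np.any(np.diff(v) > 1e-12):
            raise ValueError("cumulative volume must be non-increasing")
        object.__setattr__(self, "edges", e)
        object.__setattr__(self, "volume_cm3", v)

    @property
    def total_cm3(self) -> float:
        return float(self.volume_cm3[0])

    @property
    def volume_pct(self) -> np.ndarray:
        return 100.0 * self.volume_cm3 / self.total_cm3

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"dose_pct": self.edges, "volume_cm3": self.volume_cm3, "volume_pct": self.volume_pct}
        )


def cumulative_dvh(
    structure: list[PlanarContour],
    dose: DoseGrid,
    ct_grid: VoxelGrid,
    scheme: SupersamplingScheme | None = None,
    bin_width_pct: float = 0.1,
    slab_thickness: float | None = None,
    interpolation: str = "cubic",
) -> DVHCurve:
    """Cumulative DVH of a structure from mini-voxel dose sampling."""
    region = StructureRegion(structure, slab_thickness=slab_thickness)
    mini_vol, n_in, _, vals = _mini_dose_samples(
        dose, region, ct_grid, scheme, collect=True, interpolation=interpolation
    )
    if n_in == 0 or len(vals) == 0:
        raise ValueError("structure has zero sampled volume on the dose grid")
    return _curve_from_values(vals, mini_vol, bin_width_pct)


def d95(curve: DVHCurve) -> float:
    """Largest dose (% of prescription) received by at least 95% of the
    structure, linearly interpolated between DVH bins."""
    return dose_at_volume(curve, 95.0)


def dose_at_volume(curve: DVHCurve, volume_pct: float) -> float:
    v = curve.volume_pct
    e = curve.edges
    idx = np.nonzero(v >= volume_pct)[0]
    if len(idx) == 0:
        return 0.0
    i = idx[-1]
    if i + 1 >= len(e) or v[i] == v[i + 1]:
        return float(e[i])
    # interpolate within the bin where the curve crosses volume_pct
    frac = (v[i] - volume_pct) / (v[i] - v[i + 1])
    return float(e[i] + frac * (e[i + 1] - e[i]))


def v_at_dose(curve: DVHCurve, dose_pct: float) -> float:
    """Percentage of the structure receiving at least ``dose_pct``."""
    v = curve.volume_pct
    e = curve.edges
    if dose_pct <= e[0]:
        return float(v[0])
    if dose_pct >= e[-1]:
        return float(v[-1])
    return float(np.interp(dose_pct, e, v))


# ---------------------------------------------------------------------------
# indices


def conformity_index(tv: float, piv: float, tv_piv: float) -> float:
    """Paddick conformity index CI = TV_PIV² / (TV · PIV)."""
    if tv <= 0 or piv <= 0:
        raise ValueError("TV and PIV must be > 0")
    if tv_piv > min(tv, piv) * (1 + 1e-9):
        raise ValueError("inconsistent volumes: TV_PIV exceeds min(TV, PIV)")
    return float(tv_piv**2 / (tv * piv))


def gradient_index(v50: float, v100: float) -> float:
    """Gradient index GI = V50% / V100%."""
    if v100 <= 0:
        raise ValueError("V100 must be > 0")
    return float(v50 / v100)


@dataclass(frozen=True)
class PlanIndices:
    """Per-target SRS plan-quality summary."""

    d95_pct: float
    v_rx_pct: float  # V30Gy for a 30 Gy prescription: % of PTV at >= 100%
    ci: float
    gi: float
    v_dose_cm3: dict[float, float]
    tv_cm3: float
    piv_cm3: float
    tv_piv_cm3: float


def plan_indices(
    target: list[PlanarContour],
    region,
    dose: DoseGrid,
    ct_grid: VoxelGrid,
    scheme: SupersamplingScheme | None = None,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    slab_thickness: float | None = None,
    interpolation: str = "cubic",
) -> PlanIndices:
    """All indices for one target: V_dose at the given levels inside the
    evaluation region, D95 and V_Rx from the target DVH, Paddick CI and GI.

    PIV and TV_PIV share the mini-voxel lattice of the CT grid, so the
    Paddick precondition TV_PIV <= min(TV, PIV) holds by construction.
    """
    lev = tuple(dict.fromkeys((*levels, 100.0, 50.0)))
    vdose = isodose_volume(dose, lev, region, ct_grid, scheme, interpolation=interpolation)
    target_region = StructureRegion(target, slab_thickness=slab_thickness)
    mini_vol, n_in, counts, vals = _mini_dose_samples(
        dose, target_region, ct_grid, scheme, collect=True, levels=(100.0,),
        interpolation=interpolation,
    )
    if n_in == 0:
        raise ValueError("target has zero sampled volume")
    tv = n_in * mini_vol / 1000.0
    tv_piv = int(counts[0]) * mini_vol / 1000.0
    piv = vdose[100.0]
    curve = _curve_from_values(vals, mini_vol)
    return PlanIndices(
        d95_pct=d95(curve),
        v_rx_pct=v_at_dose(curve, 100.0),
        ci=conformity_index(tv, piv, tv_piv),
        gi=gradient_index(vdose[50.0], vdose[100.0]),
        v_dose_cm3={l: vdose[l] for l in levels},
        tv_cm3=tv,
        piv_cm3=piv,
        tv_piv_cm3=tv_piv,
    )


def _curve_from_values(vals: np.ndarray, mini_vol: float, bin_width_pct: float = 0.1) -> DVHCurve:
    # integer binning with a small upward tolerance so a dose exactly on a
    # bin edge counts into the upper bin (inclusive >= semantics)
    idx = np.floor(vals / bin_width_pct + 1e-6).astype(np.int64)
    idx = np.clip(idx, 0, None)
    n_bins = int(idx.max()) + 2
    edges = bin_width_pct * np.arange(n_bins + 1)
    hist = np.bincount(idx, minlength=n_bins).astype(float)
    cum = np.concatenate([np.cumsum(hist[::-1])[::-1], [0.0]])
    return DVHCurve(edges=edges, volume_cm3=cum * mini_vol / 1000.0)
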