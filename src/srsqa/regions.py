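"""Evaluation regions: where isodose volumes are measured.

An evaluation region isolates one target's dose from its neighbours'.  Two
families are supported:

* analytic regions — the 25%-isodose sphere of a ground-truth target, or a
  1.5-cm-wide solid expansion ("shell") of a clinical-like target surface;
* structure regions — any contour stack, rasterised with the same slab
  convention used for volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contours import PlanarContour, points_in_rings
from .rasterize import infer_slab_thickness

__all__ = ["SphereRegion", "ExpandedSurfaceRegion", "StructureRegion", "IntersectionRegion"]


@dataclass(frozen=True)
class SphereRegion:
    """All points within ``radius`` mm of ``center``."""

    center: tuple[float, float, float]
    radius: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = np.asarray(pts, dtype=float) - np.asarray(self.center)
        return (d**2).sum(axis=-1) <= self.radius**2

    def bbox(self):
        c = np.asarray(self.center)
        return (tuple(c - self.radius), tuple(c + self.radius))


@dataclass(frozen=True)
class ExpandedSurfaceRegion:
    """Solid radial expansion of a star-shaped target surface by ``width`` mm.

    Contains the whole target plus an annulus of the given width around it —
    the evaluation-shell construction that encompasses both the 100% and 50%
    isodose volumes of its target.
    """

    shape: object  # Sphere or PerturbedSphere
    width: float

    def _expanded(self):
        from .shapes import ExpandedStar

        cached = self.__dict__.get("_exp")
        if cached is None:
            cached = ExpandedStar(base=self.shape, width=self.width)
            object.__setattr__(self, "_exp", cached)
        return cached

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return self._expanded().contains(np.asarray(pts, dtype=float))

    def bbox(self):
        lo, hi = self.shape.bbox(margin=self.width)
        return (lo, hi)


@dataclass(frozen=True)
class IntersectionRegion:
    """Intersection of two regions; used to clip an evaluation shell to the
    radial range where dose can reach the lowest measured isodose level."""

    a: object
    b: object

    def contains(self, pts: np.ndarray) -> np.ndarray:
        m = self.a.contains(pts)
        if np.any(m):
            m[m] = self.b.contains(np.asarray(pts)[m])
        return m

    def bbox(self):
        (alo, ahi), (blo, bhi) = self.a.bbox(), self.b.bbox()
        return (
            tuple(max(alo[i], blo[i]) for i in range(3)),
            tuple(min(ahi[i], bhi[i]) for i in range(3)),
        )


class StructureRegion:
    """Contour-stack region under the package's slab convention."""

    def __init__(self, contours: list[PlanarContour], slab_thickness: float | None = None):
        if not contours:
            raise ValueError("empty structure region")
        self.planes: dict[float, list[PlanarContour]] = {}
        for c in contours:
            self.planes.setdefault(round(c.z, 6), []).append(c)
        self.z_planes = np.array(sorted(self.planes))
        self.h = (
            slab_thickness
            if slab_thickness is not None
            else infer_slab_thickness(self.z_planes, 1.0)
        )

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        out = np.zeros(len(pts), dtype=bool)
        z = pts[:, 2]
        j = np.searchsorted(self.z_planes, z, side="right")
        pick = np.full(len(pts), -1)
        upper_ok = (j < len(self.z_planes)) & (
            self.z_planes[np.minimum(j, len(self.z_planes) - 1)] - z <= self.h / 2
        )
        pick[upper_ok] = j[upper_ok]
        lower_ok = (~upper_ok) & (j > 0) & (
            z - self.z_planes[np.maximum(j - 1, 0)] < self.h / 2 + 1e-12
        )
        pick[lower_ok] = j[lower_ok] - 1
        for k, zp in enumerate(self.z_planes):
            sel = pick == k
            if not sel.any():
                continue
            out[sel] = points_in_rings(pts[sel, 0], pts[sel, 1], self.planes[zp])
        return out

    def bbox(self):
        xmin = min(c.bounds()[0] for cs in self.planes.values() for c in cs)
        ymin = min(c.bounds()[1] for cs in self.planes.values() for c in cs)
        xmax = max(c.bounds()[2] for cs in self.planes.values() for c in cs)
        ymax = max(c.bounds()[3] for cs in self.planes.values() for c in cs)
        return (
            (xmin, ymin, float(self.z_planes.min()) - self.h / 2),
            (xmax, ymax, float(self.z_planes.max()) + self.h / 2),
        )
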