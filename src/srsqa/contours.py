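"""Planar-contour structures.

Structures are stored the way RT Structure Sets store them: per structure, a
stack of closed planar polygons, each lying on a CT slice.  Multi-ring slices
(several polygons at the same z) are allowed and are combined with the
even-odd rule, which is what makes annular evaluation shells representable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely

__all__ = ["PlanarContour", "StructureSet", "point_in_polygon"]

_Z_DECIMALS = 6  # contours within 1e-6 mm in z are treated as coplanar


@dataclass(frozen=True)
class PlanarContour:
    """A closed simple polygon at a fixed slice position.

    ``vertices`` is an (n, 2) array of in-plane (x, y) coordinates in mm,
    implicitly closed.  Orientation is free; it is normalised internally
    where it matters.
    """

    z: float
    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        # drop an explicit closing vertex
        if len(v) > 1 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(np.unique(np.round(v, 9), axis=0)) < 3:
            raise ValueError("degenerate polygon: fewer than 3 distinct vertices")
        object.__setattr__(self, "z", float(self.z))
        object.__setattr__(self, "vertices", v)

    @property
    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)

    @property
    def area_mm2(self) -> float:
        return float(self.polygon.area)

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in mm."""
        v = self.vertices
        return (v[:, 0].min(), v[:, 1].min(), v[:, 0].max(), v[:, 1].max())


def point_in_polygon(p, contour: PlanarContour) -> bool:
    """Boundary-inclusive point containment for a single contour.

    A point exactly on the polygon boundary counts as inside (ties resolved
    toward the structure, the usual convention for inpolygon-style tests).
    """
    poly = contour.polygon
    if not poly.is_valid:
        raise ValueError("polygon is not simple (self-intersecting)")
    return bool(poly.covers(shapely.Point(float(p[0]), float(p[1]))))


def points_in_rings(x: np.ndarray, y: np.ndarray, contours: list[PlanarContour]) -> np.ndarray:
    """Vectorised even-odd containment of points against a set of coplanar rings.

    Boundary points count as inside (``intersects`` semantics); a point inside
    an even number of rings is outside, enabling annular structures.
    """
    inside = np.zeros(np.shape(x), dtype=int)
    for c in contours:
        poly = c.polygon
        shapely.prepare(poly)
        inside += shapely.intersects_xy(poly, x, y)
    return (inside % 2) == 1


@dataclass
class StructureSet:
    """Named structures, each a z-sorted stack of planar contours."""

    structures: dict[str, list[PlanarContour]] = field(default_factory=dict)
    frame_of_reference: str = ""

    def add(self, name: str, contour: PlanarContour) -> None:
        self.structures.setdefault(name, []).append(contour)
        self.structures[name].sort(key=lambda c: c.z)

    def names(self) -> list[str]:
        return list(self.structures)

    def __getitem__(self, name: str) -> list[PlanarContour]:
        return self.structures[name]

    def __contains__(self, name: str) -> bool:
        return name in self.structures

    def z_planes(self, name: str) -> np.ndarray:
        """Unique slice positions carrying contours of one structure."""
        zs = np.array([c.z for c in self.structures[name]])
        return np.unique(np.round(zs, _Z_DECIMALS))

    def grouped_by_plane(self, name: str) -> dict[float, list[PlanarContour]]:
        out: dict[float, list[PlanarContour]] = {}
        for c in self.structures[name]:
            out.setdefault(round(c.z, _Z_DECIMALS), []).append(c)
        return dict(sorted(out.items()))

    # -- JSON fixture format ------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "frame_of_reference": self.frame_of_reference,
            "structures": {
                name: [{"z": c.z, "vertices": c.vertices.tolist()} for c in cs]
                for name, cs in self.structures.items()
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "StructureSet":
        payload = json.loads(Path(path).read_text())
        ss = cls(frame_of_reference=payload.get("frame_of_reference", ""))
        for name, cs in payload["structures"].items():
            for c in cs:
                ss.add(name, PlanarContour(z=c["z"], vertices=np.asarray(c["vertices"])))
        return ss
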