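"""Analytic target shapes that know how to contour themselves on CT slices.

All shapes are star-shaped with respect to their centre: the surface is a
single-valued radial function r_s(theta, phi).  Contouring mimics a
clinician drawing on the slice image: the contour at slice position z is the
cross-section of the implicit surface at that z (no slab averaging),
discretised to a fixed number of vertices (64 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import sph_harm_y

from .contours import PlanarContour

__all__ = ["StarShape", "Sphere", "PerturbedSphere", "ExpandedStar"]

_MIN_CONTOUR_RADIUS = 1e-3  # mm; below this a cross-section is not drawable


@dataclass(frozen=True)
class StarShape:
    """Base for solids star-shaped about ``center``; subclasses define
    :meth:`radial_surface`."""

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_vertices: int = 64

    def radial_surface(self, theta, phi) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def max_radius(self) -> float:
        cached = self.__dict__.get("_max_radius")
        if cached is None:
            th = np.linspace(0, np.pi, 91)
            ph = np.linspace(-np.pi, np.pi, 181)
            tt, pp = np.meshgrid(th, ph, indexing="ij")
            cached = float(self.radial_surface(tt, pp).max())
            object.__setattr__(self, "_max_radius", cached)
        return cached

    def min_radius(self) -> float:
        cached = self.__dict__.get("_min_radius")
        if cached is None:
            th = np.linspace(0, np.pi, 91)
            ph = np.linspace(-np.pi, np.pi, 181)
            tt, pp = np.meshgrid(th, ph, indexing="ij")
            cached = float(self.radial_surface(tt, pp).min())
            object.__setattr__(self, "_min_radius", cached)
        return cached

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Membership test; the (possibly expensive) surface function is only
        evaluated in the radial band between the sampled min/max surface
        radii — points clearly inside or outside are classified directly."""
        d = np.asarray(pts, dtype=float) - np.asarray(self.center)
        rho = np.linalg.norm(d, axis=-1)
        out = rho <= self.min_radius() * 0.999
        band = ~out & (rho <= self.max_radius() * 1.001)
        if np.any(band):
            db = d[band]
            rb = rho[band]
            theta = np.arccos(np.clip(db[..., 2] / np.maximum(rb, 1e-12), -1, 1))
            phi = np.arctan2(db[..., 1], db[..., 0])
            out[band] = rb <= self.radial_surface(theta, phi)
        return out

    def bbox(self, margin: float = 0.0):
        c = np.asarray(self.center)
        r = self.max_radius()
        return (tuple(c - r - margin), tuple(c + r + margin))

    @property
    def volume_cm3(self) -> float:
        """Quadrature volume of the star-shaped solid, (1/3) ∮ r_s³ dΩ."""
        th = np.linspace(0, np.pi, 721)
        ph = np.linspace(-np.pi, np.pi, 721)
        tt, pp = np.meshgrid(th, ph, indexing="ij")
        integrand = self.radial_surface(tt, pp) ** 3 * np.sin(tt) / 3.0
        return float(np.trapezoid(np.trapezoid(integrand, ph, axis=1), th)) / 1000.0

    # -- contouring ---------------------------------------------------------

    def _plane_radii(self, dz: float, n: int | None = None) -> np.ndarray | None:
        """In-plane boundary radii rho(phi) of the axial cut ``dz`` above the
        centre, solved by bisection along each azimuth."""
        n = n or self.n_vertices
        phi = 2 * np.pi * np.arange(n) / n
        phi_w = np.where(phi > np.pi, phi - 2 * np.pi, phi)
        r_hi = self.max_radius()
        if abs(dz) >= r_hi:
            return None
        lo = np.zeros(n)
        hi = np.full(n, np.sqrt(max(r_hi**2 - dz**2, 0.0)) + 1.0)

        def f(rho):
            rr = np.sqrt(rho**2 + dz**2)
            theta = np.arctan2(rho, dz)  # rho >= 0, so theta in [0, pi]
            return rr - self.radial_surface(theta, phi_w)

        if np.any(f(lo) > 0):  # the centre line is outside the solid here
            return None
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            neg = f(mid) <= 0
            lo = np.where(neg, mid, lo)
            hi = np.where(neg, hi, mid)
        rho = 0.5 * (lo + hi)
        if rho.max() <= _MIN_CONTOUR_RADIUS:
            return None
        return rho

    def contours_at(self, z: float) -> list[PlanarContour]:
        dz = float(z) - self.center[2]
        rho = self._plane_radii(dz)
        if rho is None:
            return []
        phi = 2 * np.pi * np.arange(len(rho)) / len(rho)
        verts = np.column_stack(
            [self.center[0] + rho * np.cos(phi), self.center[1] + rho * np.sin(phi)]
        )
        try:
            return [PlanarContour(z=float(z), vertices=verts)]
        except ValueError:
            return []

    def max_axial_diameter(self) -> float:
        """Largest in-plane chord through the centre over sampled axial cuts."""
        zmax = self.max_radius()
        best = 0.0
        for z in np.linspace(-0.98 * zmax, 0.98 * zmax, 41):
            rho = self._plane_radii(z, n=128)
            if rho is None:
                continue
            chords = rho + np.roll(rho, len(rho) // 2)
            best = max(best, float(chords.max()))
        return best


@dataclass(frozen=True)
class Sphere(StarShape):
    """A sphere of radius R; contours are exact circles."""

    R: float = 1.0

    @property
    def volume_cm3(self) -> float:
        return float(4.0 / 3.0 * np.pi * self.R**3) / 1000.0

    def radial_surface(self, theta, phi):
        return np.full(np.broadcast(theta, phi).shape, float(self.R))

    def max_radius(self) -> float:
        return float(self.R)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = np.asarray(pts, dtype=float) - np.asarray(self.center)
        return (d**2).sum(axis=-1) <= self.R**2

    def contours_at(self, z: float) -> list[PlanarContour]:
        dz = float(z) - self.center[2]
        r2 = self.R**2 - dz**2
        if r2 <= _MIN_CONTOUR_RADIUS**2:
            return []
        r = np.sqrt(r2)
        ang = 2 * np.pi * np.arange(self.n_vertices) / self.n_vertices
        verts = np.column_stack(
            [self.center[0] + r * np.cos(ang), self.center[1] + r * np.sin(ang)]
        )
        return [PlanarContour(z=float(z), vertices=verts)]

    def max_axial_diameter(self) -> float:
        return 2.0 * self.R


@dataclass(frozen=True)
class PerturbedSphere(StarShape):
    """Sphere with a low-order spherical-harmonic radial perturbation, used
    for clinical-like irregular lesions:

    r_s(theta, phi) = scale * R0 * (1 + sum_lm a_lm * Re/Im Y_lm)

    ``scale`` is chosen by the generator so the maximum axial diameter
    equals the nominal diameter label.
    """

    R0: float = 1.0
    coeffs: tuple = field(default_factory=tuple)  # ((l, m, amp, use_imag), ...)
    scale: float = 1.0

    def radial_surface(self, theta, phi):
        theta = np.asarray(theta, dtype=float)
        phi = np.asarray(phi, dtype=float)
        pert = np.zeros(np.broadcast(theta, phi).shape)
        for l, m, amp, use_imag in self.coeffs:
            y = sph_harm_y(int(l), int(m), theta, phi)
            pert = pert + amp * (y.imag if use_imag else y.real)
        r = self.scale * self.R0 * (1.0 + pert)
        return np.maximum(r, 0.05 * self.R0)


@dataclass(frozen=True)
class ExpandedStar(StarShape):
    """Radial expansion of a base star shape by a fixed margin (mm); used for
    evaluation shells around clinical-like targets."""

    base: StarShape = None
    width: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "center", self.base.center)
        object.__setattr__(self, "n_vertices", self.base.n_vertices)

    def radial_surface(self, theta, phi):
        return self.base.radial_surface(theta, phi) + self.width
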