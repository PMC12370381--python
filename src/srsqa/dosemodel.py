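"""Closed-form radial dose model for SRS-like dose falloff.

The model puts 100% of the prescription at the target surface (distance
``R`` from the centre) and halves the dose every ``g`` mm beyond it, the
characteristic steep falloff of a VMAT SRS plan (~50% within a few mm of the
target).  Inside the target the same law continues to rise toward the
centre, mirroring the hot spot of a real SRS plan, optionally capped at a
maximum dose.  Every isodose surface of the isotropic model is a sphere with
a closed-form radius, which is what makes the phantoms exact oracles.

dose(r) = bath + (plateau - bath) * 2**(-(r - R) / g),  capped at ``cap``

so dose(R) = plateau (100% by default), dose(R + g) = 50% and
dose(R + 2g) = 25% for a zero bath.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DoseModelParams", "radial_dose", "analytic_isodose_radius", "analytic_isodose_volume"]


@dataclass(frozen=True)
class DoseModelParams:
    """Parameters of the radial dose model.

    Attributes
    ----------
    R : float
        Target radius in mm (D/2); the 100% isodose radius.
    g : float
        Distance in mm beyond R at which dose falls to 50% (for zero bath).
    plateau : float
        Dose (% of prescription) at the target surface, default 100.
    bath : float
        Far-field dose floor (%), default 0.
    cap : float
        Maximum interior dose (%), default 140 — the hot-spot ceiling.
    anisotropy : tuple of float
        Per-axis scale factors applied to the displacement from the centre
        before taking the radius; (1, 1, 1) is the isotropic model.
    """

    R: float
    g: float = 3.0
    plateau: float = 100.0
    bath: float = 0.0
    cap: float = 140.0
    anisotropy: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("R must be > 0")
        if self.g <= 0:
            raise ValueError("g must be > 0")
        if not (self.plateau > self.bath >= 0):
            raise ValueError("require plateau > bath >= 0")
        if self.cap < self.plateau:
            raise ValueError("cap must be >= plateau")
        if any(a <= 0 for a in self.anisotropy):
            raise ValueError("anisotropy factors must be > 0")

    @property
    def isotropic(self) -> bool:
        return all(abs(a - 1.0) < 1e-12 for a in self.anisotropy)


def radial_dose(r, params: DoseModelParams):
    """Dose (% of prescription) at radial distance(s) ``r`` mm from the centre.

    Continuous and strictly decreasing in r (until the bath floor), with
    dose(R) = plateau and a halving distance of g mm.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be >= 0")
    d = params.bath + (params.plateau - params.bath) * np.power(2.0, -(r - params.R) / params.g)
    return np.minimum(d, params.cap)


def analytic_isodose_radius(level: float, params: DoseModelParams) -> float:
    """Radius (mm) of the ``level``% isodose sphere of the isotropic model."""
    if not params.isotropic:
        raise ValueError("closed-form isodose radii require the isotropic model")
    if level <= params.bath:
        raise ValueError(f"isodose level {level}% does not close (bath = {params.bath}%)")
    if level > params.cap:
        return 0.0
    r = params.R + params.g * np.log2((params.plateau - params.bath) / (level - params.bath))
    return float(max(r, 0.0))


def analytic_isodose_volume(level: float, params: DoseModelParams) -> float:
    """Closed-form volume (cm³) enclosed by the ``level``% isodose surface."""
    r = analytic_isodose_radius(level, params)
    return float(4.0 / 3.0 * np.pi * r**3) / 1000.0
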