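"""Synthetic ground-truth phantoms and clinical-like multi-lesion cases.

Two generators:

* :func:`make_ground_truth_bundle` — analytical ground-truth bundles: for
  each requested diameter, ``n_per_diameter`` spheres with uniformly random
  sub-voxel centre offsets, contoured on the CT slice positions of a
  0.6 × 0.6 × 1 mm³ lattice, each with its own analytic radial dose matrix
  (1 × 1 × 1 mm³ by default) and a 25%-isodose evaluation volume.  The
  manifest carries the closed-form nominal values (πD³/6 volume, V100%,
  V50%, 25% radius) — never rasterized ones — so every downstream stage can
  be validated against exact numbers.

* :func:`make_clinical_like_case` — multi-lesion cases emulating an
  intracranial SRS cohort: irregular (spherical-harmonic-perturbed) targets
  with diameter labels 6–30 mm, a combined dose field (voxelwise maximum of
  per-lesion radial models plus a smooth low-dose bath, normalised so 100% =
  the 30 Gy / 5 fx prescription), 1.5-cm evaluation shells, and ≥95% target
  coverage by construction.

Randomness: one master seed per generator call; every stochastic draw
derives from it through ``numpy`` ``SeedSequence`` spawning, in target
order, so bundles are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contours import StructureSet
from .dose import DoseGrid
from .dosemodel import DoseModelParams, analytic_isodose_radius, radial_dose
from .grid import VoxelGrid
from .regions import ExpandedSurfaceRegion, SphereRegion
from .shapes import ExpandedStar, PerturbedSphere, Sphere, StarShape

__all__ = [
    "TargetRecord",
    "PhantomBundle",
    "ClinicalCaseSpec",
    "make_ground_truth_bundle",
    "make_clinical_like_case",
    "make_clinical_cohort",
]

TABLE_DIAMETER_GROUPS = (6.0, 10.0, 15.0, 20.0, 25.0, 30.0)


@dataclass(frozen=True)
class TargetRecord:
    """One target: its analytic shape, its dose model and its evaluation region."""

    name: str
    diameter_mm: float
    shape: StarShape
    dose_params: DoseModelParams
    eval_kind: str  # "isodose25" (ground truth) or "shell" (clinical-like)
    eval_size_mm: float  # 25%-isodose radius, or shell width


@dataclass
class PhantomBundle:
    """A self-contained phantom: CT lattice geometry, structures, dose model.

    The CT lattice is geometry only (no image array); dose matrices are
    materialised on demand as windows on a common dose lattice, emulating a
    recalculation at the requested dose-grid size.
    """

    ct_grid: VoxelGrid
    structures: StructureSet
    targets: list[TargetRecord]
    prescription_gy: float
    dose_spacing: tuple[float, float, float]
    dose_lattice_origin: tuple[float, float, float]
    per_target_dose: bool  # ground-truth bundles: each target has its own dose matrix
    bath: tuple[float, float, tuple[float, float, float]] | None = None  # (amp %, sigma mm, centre)
    manifest: pd.DataFrame = field(default_factory=pd.DataFrame)
    seed: int | None = None

    def save(self, directory) -> None:
        """Persist the bundle (analytic description + contours + manifest) to
        a directory: ``bundle.json``, ``structures.json``, ``manifest.csv``."""
        import json
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        payload = {
            "ct_grid": {
                "origin": self.ct_grid.origin,
                "spacing": self.ct_grid.spacing,
                "dims": self.ct_grid.dims,
            },
            "prescription_gy": self.prescription_gy,
            "dose_spacing": self.dose_spacing,
            "dose_lattice_origin": self.dose_lattice_origin,
            "per_target_dose": self.per_target_dose,
            "bath": self.bath,
            "seed": self.seed,
            "targets": [
                {
                    "name": t.name,
                    "diameter_mm": t.diameter_mm,
                    "eval_kind": t.eval_kind,
                    "eval_size_mm": t.eval_size_mm,
                    "dose_params": {
                        "R": t.dose_params.R,
                        "g": t.dose_params.g,
                        "plateau": t.dose_params.plateau,
                        "bath": t.dose_params.bath,
                        "cap": t.dose_params.cap,
                        "anisotropy": t.dose_params.anisotropy,
                    },
                    "shape": _shape_to_dict(t.shape),
                }
                for t in self.targets
            ],
        }
        (directory / "bundle.json").write_text(json.dumps(payload))
        self.structures.to_json(directory / "structures.json")
        self.manifest.to_csv(directory / "manifest.csv", index=False)

    @classmethod
    def load(cls, directory) -> "PhantomBundle":
        import json
        from pathlib import Path

        directory = Path(directory)
        payload = json.loads((directory / "bundle.json").read_text())
        g = payload["ct_grid"]
        targets = [
            TargetRecord(
                name=t["name"],
                diameter_mm=t["diameter_mm"],
                shape=_shape_from_dict(t["shape"]),
                dose_params=DoseModelParams(
                    R=t["dose_params"]["R"],
                    g=t["dose_params"]["g"],
                    plateau=t["dose_params"]["plateau"],
                    bath=t["dose_params"]["bath"],
                    cap=t["dose_params"]["cap"],
                    anisotropy=tuple(t["dose_params"]["anisotropy"]),
                ),
                eval_kind=t["eval_kind"],
                eval_size_mm=t["eval_size_mm"],
            )
            for t in payload["targets"]
        ]
        return cls(
            ct_grid=VoxelGrid(tuple(g["origin"]), tuple(g["spacing"]), tuple(g["dims"])),
            structures=StructureSet.from_json(directory / "structures.json"),
            targets=targets,
            prescription_gy=payload["prescription_gy"],
            dose_spacing=tuple(payload["dose_spacing"]),
            dose_lattice_origin=tuple(payload["dose_lattice_origin"]),
            per_target_dose=payload["per_target_dose"],
            bath=(
                (payload["bath"][0], payload["bath"][1], tuple(payload["bath"][2]))
                if payload["bath"]
                else None
            ),
            manifest=pd.read_csv(directory / "manifest.csv"),
            seed=payload["seed"],
        )

    def target(self, name: str) -> TargetRecord:
        for t in self.targets:
            if t.name == name:
                return t
        raise KeyError(name)

    def shapes(self) -> dict[str, StarShape]:
        """name → analytic shape map (targets and evaluation volumes), as
        used by ``reslice_structure`` to regenerate contours exactly."""
        out: dict[str, StarShape] = {}
        for t in self.targets:
            out[t.name] = t.shape
            if t.eval_kind == "isodose25":
                out[f"{t.name}_eval"] = Sphere(center=t.shape.center, R=t.eval_size_mm)
            else:
                out[f"{t.name}_eval"] = ExpandedStar(base=t.shape, width=t.eval_size_mm)
        return out

    def dose_model(self, target: TargetRecord | None = None):
        """Analytic dose model (points → % of prescription).

        For per-target bundles, ``target`` selects that target's own dose
        matrix; for clinical-like cases the field is the voxelwise maximum
        over all lesions plus the smooth bath.
        """
        if self.per_target_dose:
            if target is None:
                raise ValueError("per-target bundle: specify the target")
            records = [target]
        else:
            records = self.targets
        bath = self.bath

        def model(pts: np.ndarray) -> np.ndarray:
            pts = np.asarray(pts, dtype=float)
            out = np.zeros(len(pts))
            for t in records:
                d = pts - np.asarray(t.shape.center)
                d = d / np.asarray(t.dose_params.anisotropy)
                r = np.linalg.norm(d, axis=-1)
                out = np.maximum(out, radial_dose(r, t.dose_params))
            if bath is not None:
                amp, sigma, centre = bath
                r2 = ((pts - np.asarray(centre)) ** 2).sum(axis=-1)
                out = out + amp * np.exp(-r2 / (2 * sigma**2))
            return out

        return model

    def evaluation_region(self, target: TargetRecord):
        if target.eval_kind == "isodose25":
            return SphereRegion(center=target.shape.center, radius=target.eval_size_mm)
        return ExpandedSurfaceRegion(shape=target.shape, width=target.eval_size_mm)

    def dose_window(
        self,
        target: TargetRecord,
        dg_mm: float | tuple[float, float, float] | None = None,
        margin_mm: float = 6.0,
    ) -> DoseGrid:
        """Dose matrix covering the target's evaluation region plus a margin,
        sampled from the analytic model on the common dose lattice (same
        origin for every dose-grid size, as with a shared Image Position
        Patient)."""
        spacing = self.dose_spacing if dg_mm is None else (
            (dg_mm, dg_mm, dg_mm) if np.isscalar(dg_mm) else tuple(dg_mm)
        )
        region = self.evaluation_region(target)
        lo, hi = region.bbox()
        lo = tuple(v - margin_mm for v in lo)
        hi = tuple(v + margin_mm for v in hi)
        grid = VoxelGrid.from_extent(lo, hi, spacing, lattice_origin=self.dose_lattice_origin)
        model = self.dose_model(target if self.per_target_dose else None)
        return DoseGrid.from_model(model, grid, self.prescription_gy)


def _shape_to_dict(shape: StarShape) -> dict:
    if isinstance(shape, Sphere):
        return {
            "kind": "sphere",
            "center": shape.center,
            "R": shape.R,
            "n_vertices": shape.n_vertices,
        }
    if isinstance(shape, PerturbedSphere):
        return {
            "kind": "perturbed_sphere",
            "center": shape.center,
            "R0": shape.R0,
            "coeffs": [list(c) for c in shape.coeffs],
            "scale": shape.scale,
            "n_vertices": shape.n_vertices,
        }
    raise TypeError(f"cannot serialise shape {type(shape).__name__}")


def _shape_from_dict(d: dict) -> StarShape:
    if d["kind"] == "sphere":
        return Sphere(center=tuple(d["center"]), R=d["R"], n_vertices=d["n_vertices"])
    if d["kind"] == "perturbed_sphere":
        return PerturbedSphere(
            center=tuple(d["center"]),
            R0=d["R0"],
            coeffs=tuple((int(l), int(m), float(a), bool(i)) for l, m, a, i in d["coeffs"]),
            scale=d["scale"],
            n_vertices=d["n_vertices"],
        )
    raise ValueError(f"unknown shape kind {d['kind']!r}")


# ---------------------------------------------------------------------------
# ground-truth bundles


def _contour_on_grid(shape: StarShape, grid: VoxelGrid) -> list:
    out = []
    for z in grid.slice_positions:
        out.extend(shape.contours_at(float(z)))
    return out


def make_ground_truth_bundle(
    diameters: list[float] | tuple[float, ...] = (3.0, 7.0, 10.0, 15.0, 20.0),
    n_per_diameter: int = 50,
    ct_spacing: tuple[float, float, float] = (0.6, 0.6, 1.0),
    dose_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    g_mm: float = 3.0,
    prescription_gy: float = 30.0,
    n_vertices: int = 64,
    seed: int = 0,
) -> PhantomBundle:
    """Analytical ground-truth bundle of randomly centred spheres.

    Spheres are laid out on a coarse raster with one isolation cell per
    sphere (pitch twice the 25% isodose radius plus margin, so dose models
    never interact), and each centre is offset uniformly within one CT voxel.
    The manifest holds closed-form nominal values only.
    """
    diameters = [float(d) for d in diameters]
    if any(d < 3.0 or d > 30.0 for d in diameters):
        raise ValueError("diameters must lie in [3, 30] mm")
    ss = np.random.SeedSequence(seed)
    targets: list[TargetRecord] = []
    rows = []
    structures = StructureSet(frame_of_reference="srsqa-ground-truth")

    params_by_d = {d: DoseModelParams(R=d / 2.0, g=g_mm) for d in diameters}
    pitch = 2 * max(analytic_isodose_radius(25.0, p) for p in params_by_d.values()) + 16.0
    n_total = len(diameters) * n_per_diameter
    n_side = int(np.ceil(np.sqrt(n_total)))

    # CT lattice covering the raster; origin at the first voxel centre
    extent = n_side * pitch + pitch
    ct_grid = VoxelGrid.from_extent(
        (0.0, 0.0, 0.0), (extent, extent, pitch + 4.0), ct_spacing, lattice_origin=(0.0, 0.0, 0.0)
    )

    child_seeds = ss.spawn(n_total)
    idx = 0
    for d in diameters:
        params = params_by_d[d]
        r25 = analytic_isodose_radius(25.0, params)
        for j in range(n_per_diameter):
            rng = np.random.default_rng(child_seeds[idx])
            cell = (idx % n_side, idx // n_side)
            base = np.array(
                [pitch / 2 + cell[0] * pitch, pitch / 2 + cell[1] * pitch, pitch / 2]
            )
            # snap to a voxel centre, then offset uniformly within one voxel
            snapped = np.round(base / np.asarray(ct_spacing)) * np.asarray(ct_spacing)
            center = snapped + rng.uniform(0.0, 1.0, 3) * np.asarray(ct_spacing)
            name = f"sphere_D{d:g}_{j:02d}"
            shape = Sphere(center=tuple(center), R=d / 2.0, n_vertices=n_vertices)
            rec = TargetRecord(
                name=name,
                diameter_mm=d,
                shape=shape,
                dose_params=params,
                eval_kind="isodose25",
                eval_size_mm=r25,
            )
            targets.append(rec)
            for c in _contour_on_grid(shape, ct_grid):
                structures.add(name, c)
            eval_sphere = Sphere(center=tuple(center), R=r25, n_vertices=n_vertices)
            for c in _contour_on_grid(eval_sphere, ct_grid):
                structures.add(f"{name}_eval", c)
            rows.append(
                {
                    "target": name,
                    "diameter_mm": d,
                    "cx_mm": center[0],
                    "cy_mm": center[1],
                    "cz_mm": center[2],
                    "nominal_volume_cm3": np.pi * d**3 / 6.0 / 1000.0,
                    "nominal_v100_cm3": 4.0 / 3.0 * np.pi * (d / 2.0) ** 3 / 1000.0,
                    "nominal_v50_cm3": 4.0 / 3.0 * np.pi * (d / 2.0 + g_mm) ** 3 / 1000.0,
                    "r25_mm": r25,
                }
            )
            idx += 1
    manifest = pd.DataFrame(rows)
    return PhantomBundle(
        ct_grid=ct_grid,
        structures=structures,
        targets=targets,
        prescription_gy=prescription_gy,
        dose_spacing=tuple(float(s) for s in dose_spacing),
        dose_lattice_origin=(0.0, 0.0, 0.0),
        per_target_dose=True,
        manifest=manifest,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# clinical-like cases


@dataclass(frozen=True)
class ClinicalCaseSpec:
    """Specification of one multi-lesion clinical-like case.

    ``diameters_mm`` are maximum-axial-diameter labels from the cohort
    groups {6, 10, 15, 20, 25, 30}; the prescription is 30 Gy in 5
    fractions; ``irregularity`` scales the spherical-harmonic surface
    perturbation; ``coverage`` is the target-volume fraction guaranteed to
    receive the prescription by construction.
    """

    diameters_mm: tuple[float, ...]
    irregularity: float = 0.08
    coverage: float = 0.97
    shell_width_mm: float = 15.0
    prescription_gy: float = 30.0
    bath_pct: float = 3.0
    head_mm: float = 180.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.diameters_mm:
            raise ValueError("at least one lesion required")
        if any(d not in TABLE_DIAMETER_GROUPS for d in self.diameters_mm):
            raise ValueError(f"diameter labels must be in {TABLE_DIAMETER_GROUPS}")
        if not (0.95 <= self.coverage < 1.0):
            raise ValueError("coverage must be in [0.95, 1)")


def make_clinical_cohort(
    n_cases: int = 15,
    seed: int = 0,
    groups: tuple[float, ...] = TABLE_DIAMETER_GROUPS,
    **case_kwargs,
) -> list[PhantomBundle]:
    """A cohort of clinical-like cases spanning the diameter groups.

    Case ``i`` carries ``1 + i % 3`` lesions with diameter labels cycling
    through ``groups``, so a 15-case cohort covers every group several times
    with mixed multi-lesion configurations.  Per-case seeds derive from the
    master seed (``seed * 10_000 + i``).
    """
    bundles = []
    for i in range(n_cases):
        n_lesions = 1 + i % 3
        lesions = tuple(groups[(i + 2 * j) % len(groups)] for j in range(n_lesions))
        spec = ClinicalCaseSpec(diameters_mm=lesions, seed=seed * 10_000 + i, **case_kwargs)
        bundles.append(make_clinical_like_case(spec))
    return bundles


def _coverage_radius(shape: StarShape, coverage: float) -> float:
    """Radius of the sphere covering ``coverage`` of the star solid's volume."""
    th = np.linspace(0, np.pi, 181)
    ph = np.linspace(-np.pi, np.pi, 361)
    tt, pp = np.meshgrid(th, ph, indexing="ij")
    w = np.sin(tt)
    r_s = shape.radial_surface(tt, pp)
    total = (r_s**3 * w).sum()

    def frac(R):
        return (np.minimum(r_s, R) ** 3 * w).sum() / total

    lo, hi = 0.0, float(r_s.max())
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if frac(mid) < coverage:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _clinical_g(r_dose: float) -> float:
    # dose-falloff halving distance grows with lesion size, keeping the
    # gradient index in the clinically reported range across 6-30 mm lesions
    return 3.0 + 0.25 * r_dose


def make_clinical_like_case(
    spec: ClinicalCaseSpec,
    ct_spacing: tuple[float, float, float] = (0.6, 0.6, 1.0),
    dose_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    name_prefix: str = "ptv",
) -> PhantomBundle:
    """Generate one clinical-like multi-lesion bundle from a seeded spec."""
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss)
    half = spec.head_mm / 2.0

    shapes: list[PerturbedSphere] = []
    params: list[DoseModelParams] = []
    centers: list[np.ndarray] = []
    # provisional radii for the separation constraint
    for d in spec.diameters_mm:
        # low-order harmonic perturbation; amplitudes shrink with degree
        coeffs = []
        for l in (2, 3):
            for m in range(0, l + 1):
                amp = spec.irregularity * rng.normal() / (l - 1)
                use_imag = bool(m > 0 and rng.random() < 0.5)
                coeffs.append((l, m, float(amp), use_imag))
        shape0 = PerturbedSphere(center=(0.0, 0.0, 0.0), R0=d / 2.0, coeffs=tuple(coeffs))
        scale = d / shape0.max_axial_diameter()
        shape0 = PerturbedSphere(center=(0.0, 0.0, 0.0), R0=d / 2.0, coeffs=tuple(coeffs), scale=scale)
        r_dose = _coverage_radius(shape0, spec.coverage)
        g = _clinical_g(r_dose)
        aniso = tuple(rng.uniform(0.95, 1.05, 3))
        params.append(DoseModelParams(R=r_dose, g=g, anisotropy=aniso))
        shapes.append(shape0)

    # separation: another lesion's dose must be negligible (< ~1%) inside
    # this lesion's shell, and shells must not include other 100% isodoses
    def min_sep(i: int, j: int) -> float:
        ri = shapes[i].max_radius() + spec.shell_width_mm
        rj_low = params[j].R + params[j].g * np.log2(100.0)  # ~1% isodose radius
        return ri + rj_low

    for attempt in range(2000):
        centers = [
            rng.uniform(-half + 40.0, half - 40.0, 3) for _ in spec.diameters_mm
        ]
        ok = all(
            np.linalg.norm(centers[i] - centers[j]) >= max(min_sep(i, j), min_sep(j, i))
            for i in range(len(centers))
            for j in range(i + 1, len(centers))
        )
        if ok:
            break
    else:
        raise ValueError("could not place lesions with the required separation")

    ct_grid = VoxelGrid.from_extent(
        (-half, -half, -half), (half, half, half), ct_spacing, lattice_origin=(0.0, 0.0, 0.0)
    )
    # snap each centre to a CT voxel centre plus a uniform sub-voxel offset
    sp = np.asarray(ct_spacing)
    centers = [np.round(c / sp) * sp + rng.uniform(0, 1, 3) * sp for c in centers]

    structures = StructureSet(frame_of_reference=f"srsqa-clinical-{spec.seed}")
    targets: list[TargetRecord] = []
    rows = []
    for i, d in enumerate(spec.diameters_mm):
        name = f"{name_prefix}{i+1}_D{d:g}"
        shape = PerturbedSphere(
            center=tuple(centers[i]),
            R0=shapes[i].R0,
            coeffs=shapes[i].coeffs,
            scale=shapes[i].scale,
        )
        rec = TargetRecord(
            name=name,
            diameter_mm=d,
            shape=shape,
            dose_params=params[i],
            eval_kind="shell",
            eval_size_mm=spec.shell_width_mm,
        )
        targets.append(rec)
        for c in _contour_on_grid(shape, ct_grid):
            structures.add(name, c)
        shell = ExpandedStar(base=shape, width=spec.shell_width_mm)
        for c in _contour_on_grid(shell, ct_grid):
            structures.add(f"{name}_eval", c)
        rows.append(
            {
                "target": name,
                "diameter_mm": d,
                "cx_mm": centers[i][0],
                "cy_mm": centers[i][1],
                "cz_mm": centers[i][2],
                "target_volume_cm3": shape.volume_cm3,
                "dose_radius_mm": params[i].R,
                "g_mm": params[i].g,
            }
        )

    return PhantomBundle(
        ct_grid=ct_grid,
        structures=structures,
        targets=targets,
        prescription_gy=spec.prescription_gy,
        dose_spacing=tuple(float(s) for s in dose_spacing),
        dose_lattice_origin=(0.0, 0.0, 0.0),
        per_target_dose=False,
        bath=(spec.bath_pct, 60.0, (0.0, 0.0, 0.0)),
        manifest=pd.DataFrame(rows),
        seed=spec.seed,
    )
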