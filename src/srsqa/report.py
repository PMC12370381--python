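"""Human-readable study reports: tidy CSV/JSON outputs and figures."""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .study import StudyResult

__all__ = ["write_study_report", "plot_ratio_fit", "plot_pct_diff_boxes"]


def plot_ratio_fit(result: StudyResult, ptype: str, value: float, path: str | Path) -> Path:
    """Scatter of V_dose(eval)/V_dose(ref) against V_dose(ref) with the
    fitted power-law curve for one perturbation."""
    levels = [f"V{lev:g}" for lev in result.config.levels_pct]
    rec = result.records
    grp = rec[(rec.perturbation == ptype) & (rec.value_mm == value) & rec.quantity.isin(levels)]
    fit = result.fits[(ptype, value)]
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.scatter(grp["ref"], grp["ratio"], s=14, alpha=0.6, label="targets × levels")
    xs = np.geomspace(max(grp["ref"].min(), 1e-3), grp["ref"].max(), 200)
    ax.plot(xs, fit.predict(xs), "r-", label=f"y = a·x^b + c (NRMSE {fit.nrmse:.3f})")
    ax.axhline(1.0, color="k", lw=0.6)
    ax.set_xscale("log")
    ax.set_xlabel("V_dose(ref) [cm³]")
    ax.set_ylabel("V_dose(eval) / V_dose(ref)")
    ax.set_title(f"{ptype} = {value:g} mm vs reference")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_pct_diff_boxes(result: StudyResult, ptype: str, value: float, path: str | Path) -> Path:
    """Box plots of local % differences per diameter group for the DVH indices."""
    rec = result.records
    quantities = ["V30Gy", "CI", "GI", "D95"]
    fig, axes = plt.subplots(1, len(quantities), figsize=(3.2 * len(quantities), 3.6), sharex=True)
    for ax, qty in zip(np.atleast_1d(axes), quantities):
        grp = rec[(rec.perturbation == ptype) & (rec.value_mm == value) & (rec.quantity == qty)]
        dias = sorted(grp["diameter_mm"].unique())
        data = [grp[grp.diameter_mm == d]["pct_diff"].to_numpy() for d in dias]
        ax.boxplot(data, tick_labels=[f"{d:g}" for d in dias])
        ax.axhline(0.0, color="k", lw=0.6)
        ax.set_title(qty, fontsize=10)
        ax.set_xlabel("PTV diameter [mm]")
    np.atleast_1d(axes)[0].set_ylabel("local difference [%]")
    fig.suptitle(f"{ptype} = {value:g} mm vs reference", fontsize=11)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def write_study_report(result: StudyResult, directory: str | Path) -> dict[str, Path]:
    """Write records.csv, stats.csv, fits.json and the figures for every
    non-reference perturbation into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    out["records"] = directory / "records.csv"
    result.records.to_csv(out["records"], index=False)
    out["stats"] = directory / "stats.csv"
    result.stats.to_csv(out["stats"], index=False)
    fits_payload = {
        f"{ptype}_{value:g}mm": {
            "a": f.a,
            "b": f.b,
            "c": f.c,
            "nrmse": f.nrmse,
            "spearman_rho": f.rho,
            "spearman_p": f.p,
            "n": f.n,
        }
        for (ptype, value), f in result.fits.items()
    }
    out["fits"] = directory / "fits.json"
    out["fits"].write_text(json.dumps(fits_payload, indent=2))
    for (ptype, value) in result.fits:
        key = f"ratio_{ptype}_{value:g}mm"
        out[key] = plot_ratio_fit(result, ptype, value, directory / f"{key}.png")
        key2 = f"boxes_{ptype}_{value:g}mm"
        out[key2] = plot_pct_diff_boxes(result, ptype, value, directory / f"{key2}.png")
    return out
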