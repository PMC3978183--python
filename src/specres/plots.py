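"""Publication-style plots of the resolution trends."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .trends import fit_linear, fit_powerlaw
from .metrics import ResolutionRecord


def _records(df: pd.DataFrame) -> list[ResolutionRecord]:
    return [ResolutionRecord(r.radius_cm, r.rr_mm, r.tr_mm,
                             getattr(r, "rr_err_mm", float("nan")),
                             getattr(r, "tr_err_mm", float("nan")),
                             bool(r.valid))
            for r in df.itertuples()]


def plot_resolution_vs_radius(df: pd.DataFrame, ax=None, title: str = ""):
    """RR and TR vs radius with their linear fits, for one recon setting."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sub = df[df.valid]
    recs = _records(sub)
    rr_line = fit_linear(recs, "rr")
    tr_line = fit_linear(recs, "tr")
    r = np.linspace(sub.radius_cm.min(), sub.radius_cm.max(), 50)
    ax.errorbar(sub.radius_cm, sub.rr_mm, yerr=sub.rr_err_mm, fmt="o",
                label="radial", capsize=2)
    ax.errorbar(sub.radius_cm, sub.tr_mm, yerr=sub.tr_err_mm, fmt="s",
                label="tangential", capsize=2)
    ax.plot(r, rr_line.predict(r), "-", color="C0")
    ax.plot(r, tr_line.predict(r), "--", color="C1")
    ax.set_xlabel("radial distance from isocenter (cm)")
    ax.set_ylabel("FWHM (mm)")
    if title:
        ax.set_title(title)
    ax.legend()
    return ax


def plot_convergence(df: pd.DataFrame, radius_cm: float, component: str = "tr_mm",
                     ax=None, title: str = ""):
    """FWHM vs IT x SUB at one radius with the power-law fit."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sub = df[(df.radius_cm == radius_cm) & df.valid & (df.algorithm == "OSEM")]
    pairs = list(zip(sub.it_sub, sub[component]))
    fitp = fit_powerlaw(pairs)
    n = np.geomspace(sub.it_sub.min(), sub.it_sub.max(), 50)
    ax.loglog(sub.it_sub, sub[component], "o")
    ax.loglog(n, fitp.predict(n), "-", label=fitp.summary())
    ax.set_xlabel(r"IT $\times$ SUB")
    ax.set_ylabel("FWHM (mm)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax


def save_report_figures(df: pd.DataFrame, outdir) -> list[str]:
    """Write the standard trend figures for a results table; returns paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for (matrix, algo, it, sub), g in df.groupby(
            ["matrix", "algorithm", "iterations", "subsets"]):
        if g.valid.sum() < 3:
            continue
        label = f"{algo.lower()}_{it}x{sub}" if algo == "OSEM" else "fbp"
        fig, ax = plt.subplots(figsize=(5, 4))
        plot_resolution_vs_radius(g, ax=ax, title=f"{matrix} matrix, {label}")
        path = outdir / f"resolution_vs_radius_{matrix}_{label}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(str(path))
    osem = df[(df.algorithm == "OSEM") & df.valid]
    if osem.it_sub.nunique() >= 3:
        for radius in sorted(osem.radius_cm.unique()):
            if osem[osem.radius_cm == radius].it_sub.nunique() < 3:
                continue
            fig, ax = plt.subplots(figsize=(5, 4))
            plot_convergence(osem, radius, ax=ax,
                             title=f"tangential convergence at {radius:g} cm")
            path = outdir / f"convergence_r{radius:g}cm.png"
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
            written.append(str(path))
            break
    return written
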