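"""Post-hoc figures: energy profiles, trait histograms, KDEs, sweep surfaces."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .engine import SimLog
from .metrics import factor_histogram, kde_mode
from .sweep import SweepResult

__all__ = ["plot_energy", "plot_factor_histograms", "plot_trait_kde", "plot_sweep_surfaces", "plot_run", "plot_sweep"]


def plot_energy(log: SimLog, ax: Optional[plt.Axes] = None) -> plt.Axes:
    """Prey max/mean/min (cyan) and predator (red) energy over time."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.2))
    t = np.arange(log.n_steps + 1)
    ax.plot(t, log.prey_energy.max(axis=1), color="c", lw=0.7, alpha=0.6, label="prey max")
    ax.plot(t, log.mean_prey_energy(), color="c", lw=1.6, label="prey mean")
    ax.plot(t, log.prey_energy.min(axis=1), color="c", lw=0.7, alpha=0.6, label="prey min")
    ax.plot(t, log.pred_energy, color="r", lw=1.4, label="predator")
    for d in log.deaths:
        ax.plot(d.time_step, 0.0, marker="v", color="k", ms=3)
    ax.set_xlabel("time step")
    ax.set_ylabel("energy")
    ax.legend(fontsize=7, ncol=4)
    return ax


def plot_factor_histograms(log: SimLog, axes=None):
    """Initial (outlined) vs final (filled) 20-bin factor histograms."""
    cfg = log.config
    if axes is None:
        _, axes = plt.subplots(2, 1, figsize=(4, 4.5))
    for ax, (name, vals0, valsT, rng) in zip(
        axes,
        [
            ("fe", log.prey_fe[0], log.prey_fe[-1], cfg.fe_range),
            ("fg", log.prey_fg[0], log.prey_fg[-1], cfg.fg_range),
        ],
    ):
        edges = np.linspace(rng[0], rng[1], cfg.n_hist_bins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        width = edges[1] - edges[0]
        h0 = factor_histogram(vals0, rng, cfg.n_hist_bins)
        hT = factor_histogram(valsT, rng, cfg.n_hist_bins)
        ax.bar(centers, hT, width=width * 0.9, color="tab:blue", label="final")
        ax.step(edges[:-1], h0, where="post", color="k", ls=":", label="initial")
        ax.set_xlabel(name)
        ax.set_ylabel("count")
        ax.legend(fontsize=7)
    return axes


def plot_trait_kde(log: SimLog, axes=None):
    """Smoothed (6x Silverman bandwidth) final factor densities with rug marks."""
    cfg = log.config
    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(7, 2.8))
    for ax, (name, vals, rng) in zip(
        axes,
        [("fe", log.prey_fe[-1], cfg.fe_range), ("fg", log.prey_fg[-1], cfg.fg_range)],
    ):
        grid, density, mode = kde_mode(vals, cfg.kde_bandwidth_factor, rng)
        ax.plot(grid, density, lw=1.4)
        ax.plot(vals, np.zeros_like(vals), "x", ms=4, color="gray")
        ax.axvline(mode, color="r", lw=0.8, ls="--")
        ax.set_xlabel(name)
        ax.set_ylabel("density")
    return axes


def plot_sweep_surfaces(result: SweepResult, out_dir: str | Path) -> list[Path]:
    """One colour-mapped mean surface over (L, phi_w) per metric."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    agg = result.aggregate()
    written = []
    for metric in ("tsd", "d_ed", "tsy", "ets", "dm_fe", "dm_fg"):
        table = agg[metric]["mean"].unstack("phi_w")
        fig, ax = plt.subplots(figsize=(4, 3.2))
        im = ax.pcolormesh(
            table.index.to_numpy(), table.columns.to_numpy(), table.to_numpy().T,
            shading="nearest", cmap="RdYlGn",
        )
        fig.colorbar(im, ax=ax, label=metric)
        ax.set_xlabel("arena length L")
        ax.set_ylabel("odor injection width")
        ax.set_title(metric)
        p = out_dir / f"sweep_{metric}.png"
        fig.savefig(p, dpi=110, bbox_inches="tight")
        plt.close(fig)
        written.append(p)
    return written


def plot_run(log: SimLog, out_dir: str | Path) -> list[Path]:
    """Energy + histogram + KDE panels for a single run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    ax = plot_energy(log)
    p = out_dir / "energy.png"
    ax.figure.savefig(p, dpi=110, bbox_inches="tight")
    plt.close(ax.figure)
    written.append(p)
    axes = plot_factor_histograms(log)
    p = out_dir / "factor_histograms.png"
    axes[0].figure.savefig(p, dpi=110, bbox_inches="tight")
    plt.close(axes[0].figure)
    written.append(p)
    axes = plot_trait_kde(log)
    p = out_dir / "trait_kde.png"
    axes[0].figure.savefig(p, dpi=110, bbox_inches="tight")
    plt.close(axes[0].figure)
    written.append(p)
    return written


def plot_sweep(result: SweepResult, out_dir: str | Path) -> list[Path]:
    """All sweep figure families (degenerate single-condition grids included)."""
    return plot_sweep_surfaces(result, out_dir)
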