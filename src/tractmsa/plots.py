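"""Matplotlib renderings of the standard diagnostic panels."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from matplotlib.figure import Figure

from .disconnection import CorrelationResult
from .shapley import ContributionResult


def plot_correlation_heatmap(result: CorrelationResult, path: str | Path) -> None:
    """Heatmap of pairwise lesion-pattern correlations.

    Non-significant entries (p >= level) are blacked out; undefined
    (zero-variance) players render as missing.
    """
    r = result.r.to_numpy().copy()
    r[result.masked.to_numpy()] = np.nan
    fig = Figure(figsize=(6, 5))
    ax = fig.add_subplot()
    cmap = __import__("matplotlib").colormaps["coolwarm"].copy()
    cmap.set_bad("black")
    im = ax.imshow(r, vmin=-1, vmax=1, cmap=cmap)
    names = list(result.r.columns)
    ax.set_xticks(range(len(names)), names, rotation=90, fontsize=7)
    ax.set_yticks(range(len(names)), names, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_title(f"lesion-pattern correlations (p < {result.level:g} shown)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)


def plot_contributions(result: ContributionResult, path: str | Path) -> None:
    """Bar plot of normalized contributions with bootstrap-SD error bars."""
    fig = Figure(figsize=(7, 4))
    ax = fig.add_subplot()
    x = np.arange(len(result.player_names))
    scale = np.abs(result.mean).sum()
    sd = result.boot_sd / scale if scale > 0 else result.boot_sd
    colors = ["tab:blue" if m >= 0 else "tab:red" for m in result.mean]
    ax.bar(x, result.normalized, yerr=sd, color=colors, capsize=2)
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xticks(x, result.player_names, rotation=90, fontsize=8)
    ax.set_ylabel("normalized contribution")
    ax.set_title(f"{result.test}: mean contribution ± bootstrap SD "
                 f"({result.n_boot} resamples, {result.n_perms} permutations)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
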