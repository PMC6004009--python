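"""Figures: fitted curves per condition and the CS-vs-size synthesis panel."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .model import UNFLANKED, CrowdingParams, psi
from .synth import aggregate

__all__ = ["curve_figure", "cs_vs_size_figure"]


def curve_figure(trials: pd.DataFrame, params_by_cell, path) -> None:
    """Proportion correct vs. gap per cell: points, fitted curve, unflanked square."""
    cells = sorted(params_by_cell)
    ncol = min(4, len(cells))
    nrow = int(np.ceil(len(cells) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow), squeeze=False)
    agg = aggregate(trials)
    grid = np.linspace(0, 1.8, 200)
    for ax, cell in zip(axes.ravel(), cells):
        subject, optical, stroke = cell
        params: CrowdingParams = params_by_cell[cell]
        sel = agg[
            (agg["subject"] == subject)
            & (agg["optical"] == optical)
            & (agg["stroke_arcmin"] == stroke)
        ]
        finite = sel[[g is not UNFLANKED for g in sel["gap_arcmin"]]]
        ax.plot(
            [float(g) for g in finite["gap_arcmin"]],
            finite["n_correct"] / finite["n_total"],
            "o", ms=4, color="k",
        )
        unf = sel[[g is UNFLANKED for g in sel["gap_arcmin"]]]
        if len(unf):
            ax.plot([1.75], unf["n_correct"] / unf["n_total"], "s", ms=5, color="tab:blue")
        ax.plot(grid, psi(grid, params), color="tab:red", lw=1.5)
        ax.set_ylim(0.2, 1.02)
        ax.set_title(f"{subject} {optical} {stroke}'", fontsize=9)
    for ax in axes.ravel()[len(cells):]:
        ax.axis("off")
    fig.supxlabel("edge-to-edge gap (arcmin)")
    fig.supylabel("proportion correct")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def cs_vs_size_figure(spacing_table: pd.DataFrame, path) -> None:
    """Log-log center-to-center critical spacing vs. letter size.

    The dotted reference line is the foveal size-limited regime
    (CS = 1.4 x size); starred cells have 80-95% unflanked accuracy.
    """
    sp = spacing_table[spacing_table["cs_defined"]]
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for (subject, optical), grp in sp.groupby(["subject", "optical"]):
        marker = "o" if optical == "AO" else "^"
        ax.plot(
            grp["letter_arcmin"], grp["cs_cc_arcmin"],
            marker=marker, ls="-", ms=5, label=f"{subject} {optical}",
        )
    stars = sp[sp["star_80_95"]]
    if len(stars):
        ax.plot(stars["letter_arcmin"], stars["cs_cc_arcmin"], "k*", ms=10, ls="none")
    sizes = np.array([sp["letter_arcmin"].min() * 0.8, sp["letter_arcmin"].max() * 1.2])
    ax.plot(sizes, 1.4 * sizes, "k:", label="CS = 1.4 x size")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("letter size (arcmin)")
    ax.set_ylabel("center-to-center critical spacing (arcmin)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
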