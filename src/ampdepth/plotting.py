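"""Figures: per-level kappa/OOB boxplots, rarefaction curves, NMDS ellipses,
CV kernel densities.  All functions draw onto (and return) a matplotlib Axes
or Figure; callers save with ``fig.savefig``."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "plot_sweep_boxes",
    "plot_rarefaction_curves",
    "plot_ordination",
    "plot_cv_density",
]

_BAND_COLORS = {"almost_perfect": "#2ca02c", "moderate": "#ff7f0e", "poor": "#d62728"}


def plot_sweep_boxes(records: pd.DataFrame, title: str = ""):
    """Two-panel boxplot of kappa and OOB error per depth level.

    ``records`` is the all-levels model-record frame (columns: depth, kappa,
    oob_error); kappa band edges at 0.6 and 0.8 are drawn as guides.
    """
    depths = list(dict.fromkeys(records["depth"]))
    fig, axes = plt.subplots(2, 1, figsize=(9, 6), sharex=True)
    for ax, col, label in ((axes[0], "kappa", "Cohen's kappa"),
                           (axes[1], "oob_error", "OOB error")):
        data = [records.loc[records["depth"] == d, col].to_numpy() for d in depths]
        ax.boxplot(data, tick_labels=[str(d) for d in depths])
        ax.set_ylabel(label)
    axes[0].axhline(0.8, color=_BAND_COLORS["almost_perfect"], ls="--", lw=1)
    axes[0].axhline(0.6, color=_BAND_COLORS["poor"], ls="--", lw=1)
    axes[1].set_xlabel("sequences per sample")
    if title:
        fig.suptitle(title)
    fig.autofmt_xdate(rotation=45)
    fig.tight_layout()
    return fig


def plot_rarefaction_curves(curves: dict, ladder=None):
    """Expected-richness curves per sample.

    ``curves`` maps sample id -> (depths array, expected richness array);
    ladder levels, if given, are drawn as vertical guides.
    """
    fig, ax = plt.subplots(figsize=(8, 5))
    for sample, (depths, richness) in curves.items():
        ax.plot(depths, richness, lw=0.8, alpha=0.7, label=str(sample))
    if ladder:
        for level in ladder:
            ax.axvline(level, color="grey", lw=0.5, ls=":")
    ax.set_xlabel("reads subsampled")
    ax.set_ylabel("expected ASVs observed")
    if len(curves) <= 12:
        ax.legend(fontsize="x-small")
    fig.tight_layout()
    return fig


def plot_ordination(ordination):
    """NMDS scatter colored by class, with per-class confidence ellipses."""
    fig, ax = plt.subplots(figsize=(6, 6))
    coords = ordination.coordinates
    for i, cls in enumerate(sorted(coords["label"].unique())):
        sub = coords[coords["label"] == cls]
        color = f"C{i}"
        ax.scatter(sub["axis1"], sub["axis2"], s=25, color=color, label=str(cls))
        ring = ordination.ellipses[cls].boundary()
        ax.plot(ring[:, 0], ring[:, 1], color=color, lw=1.2)
    ax.set_xlabel("NMDS axis 1")
    ax.set_ylabel("NMDS axis 2")
    ax.set_title(f"stress = {ordination.stress:.3f}")
    ax.legend(fontsize="small")
    fig.tight_layout()
    return fig


def plot_cv_density(cv_results: dict):
    """Kernel densities of per-feature CV distributions, one line per dataset."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name, res in cv_results.items():
        dens = res.density()
        finite = np.isfinite(dens["density"])
        ax.plot(dens.loc[finite, "cv"], dens.loc[finite, "density"], label=str(name))
    ax.set_xlabel("per-feature CV of class means")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    return fig
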