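"""Figure helpers: fate proportions, connectivity heatmaps, density maps."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .mortality import FATE_COLUMNS

FATE_COLORS = {
    "alive": "#2a9d8f",
    "dead_hypothermia": "#264653",
    "dead_hyperthermia": "#e76f51",
    "advected_out": "#e9c46a",
}


def fate_proportions(bundle) -> plt.Figure:
    """Stacked per-site fate proportions, one panel per (window, season)."""
    keys = [(w, s) for w in bundle.config.windows for s in bundle.config.seasons]
    fig, axes = plt.subplots(
        len(bundle.config.windows), len(bundle.config.seasons),
        figsize=(5.2 * len(bundle.config.seasons), 3.4 * len(bundle.config.windows)),
        squeeze=False,
    )
    table = bundle.mortality_table()
    for ax, (window, season) in zip(axes.ravel(), keys):
        sub = table[(table.window == window) & (table.season == season)]
        agg = sub.groupby("site", sort=False)[list(("released",) + FATE_COLUMNS)].sum()
        agg = agg.reindex(list(bundle.config.registry.ids))
        frac = agg[list(FATE_COLUMNS)].div(agg["released"], axis=0)
        bottom = np.zeros(len(frac))
        for col in FATE_COLUMNS:
            ax.bar(frac.index, frac[col], bottom=bottom, color=FATE_COLORS[col], label=col)
            bottom += frac[col].to_numpy()
        ax.set_title(f"{window}, {season}")
        ax.set_ylim(0, 1)
        ax.set_ylabel("proportion")
    axes[0, -1].legend(fontsize=7, loc="upper right")
    fig.tight_layout()
    return fig


def tpm_heatmap(tpm) -> plt.Figure:
    """Source×sink transition-probability heatmap; diagonal = local retention."""
    fig, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.imshow(tpm.P, cmap="viridis", vmin=0, vmax=max(tpm.P.max(), 1e-6))
    k = len(tpm.site_ids)
    ax.set_xticks(range(k), tpm.site_ids, rotation=45)
    ax.set_yticks(range(k), tpm.site_ids)
    ax.set_xlabel("sink")
    ax.set_ylabel("source")
    ax.plot([-0.5, k - 0.5], [-0.5, k - 0.5], color="k", lw=0.8)
    fig.colorbar(im, ax=ax, label="P(recruit)")
    fig.tight_layout()
    return fig


def density_plot(dm, registry=None) -> plt.Figure:
    """Survivorship-weighted larval crossing-likelihood map."""
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.pcolormesh(dm.lons, dm.lats, dm.values, cmap="magma", shading="auto")
    if registry is not None:
        for site in registry:
            ax.plot(*site.centroid, "wo", ms=4, mec="k")
            ax.annotate(site.id, site.centroid, color="w", fontsize=7,
                        xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("lon")
    ax.set_ylabel("lat")
    fig.colorbar(im, ax=ax, label="crossing likelihood")
    fig.tight_layout()
    return fig
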