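"""Simple diagnostic plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

CATEGORY_COLORS = {
    "cis": "black",
    "trans": "tab:red",
    "cis_plus_trans": "tab:blue",
    "cis_x_trans": "tab:orange",
    "compensatory": "tab:green",
    "conserved": "lightgray",
    "ambiguous": "tab:purple",
}


def parent_vs_hybrid_scatter(calls, overall, path, tissue=None):
    """Scatter of parent (cis+trans) vs hybrid (cis) log2 ratios by category."""
    df = calls.merge(
        overall[["gene_id", "tissue", "log2_hybrid_overall", "log2_parent_overall"]],
        on=["gene_id", "tissue"],
    )
    if tissue is not None:
        df = df[df["tissue"] == tissue]
    fig, ax = plt.subplots(figsize=(6, 6))
    for cat, color in CATEGORY_COLORS.items():
        sub = df[df["category"] == cat]
        if len(sub):
            ax.scatter(
                sub["log2_parent_overall"],
                sub["log2_hybrid_overall"],
                s=4,
                c=color,
                label=f"{cat} ({len(sub)})",
                alpha=0.6,
                linewidths=0,
            )
    ax.axhline(0, color="gray", lw=0.5)
    ax.axvline(0, color="gray", lw=0.5)
    ax.set_xlabel("parent log2 maize:teosinte (cis + trans)")
    ax.set_ylabel("hybrid log2 maize:teosinte (cis)")
    ax.legend(markerscale=2, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cis_share_bin_plot(bins, path):
    """Mean cis share per total-divergence bin with CI error bars."""
    fig, ax = plt.subplots(figsize=(5, 4))
    x = range(len(bins))
    y = bins["mean_cis_share"]
    yerr = [
        (y - bins["ci_low"]).fillna(0),
        (bins["ci_high"] - y).fillna(0),
    ]
    ax.errorbar(x, y, yerr=yerr, fmt="o-", capsize=3)
    ax.set_xticks(list(x), bins["bin"])
    ax.set_xlabel("|log2 parent ratio| bin")
    ax.set_ylabel("mean |cis| / (|cis| + |trans|)")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
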