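"""How much regulatory divergence is cis: shares, bins, and F1 influence.

The per-gene cis share is |cis| / (|cis| + |trans|) computed from the
overall log2 hybrid ratio (cis) and the parent-minus-hybrid difference
(trans).  Binning genes by total divergence |log2 parent ratio| shows
whether large expression differences are driven by cis or trans.  A
leave-one-out analysis drops each F1's counts from the overall hybrid
ratio to measure single-cross influence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BIN_EDGES = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, np.inf)
BIN_LABELS = ("0-1", "1-2", "2-3", "3-4", "4-5", "5+")


def cis_share(log2_hybrid: float, trans_effect: float) -> float:
    """|cis| / (|cis| + |trans|); NaN when both effects are exactly zero."""
    a, b = abs(log2_hybrid), abs(trans_effect)
    if not np.isfinite(a) or not np.isfinite(b):
        return np.nan
    if a + b == 0:
        return np.nan
    return a / (a + b)


def cis_share_by_bin(
    overall: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Mean cis share per total-divergence bin with bootstrap 95% CIs.

    Genes with undefined log ratios (zero counts) or with both effects
    exactly zero are excluded.  The bootstrap resamples genes within bins;
    ``n_boot=0`` omits the CIs.
    """
    if overall.empty:
        return pd.DataFrame(
            columns=["bin", "n_genes", "mean_cis_share", "ci_low", "ci_high"]
        )
    df = overall.copy()
    cis = df["log2_hybrid_overall"]
    trans = df["log2_parent_overall"] - df["log2_hybrid_overall"]
    share = (cis.abs()) / (cis.abs() + trans.abs())
    df["cis_share"] = share
    df["total_divergence"] = df["log2_parent_overall"].abs()
    df = df[np.isfinite(df["cis_share"]) & np.isfinite(df["total_divergence"])]
    if df.empty:
        return pd.DataFrame(
            columns=["bin", "n_genes", "mean_cis_share", "ci_low", "ci_high"]
        )
    df["bin"] = pd.cut(
        df["total_divergence"],
        bins=BIN_EDGES,
        labels=BIN_LABELS,
        right=False,
        include_lowest=True,
    )
    rng = np.random.default_rng(seed)
    rows = []
    for label in BIN_LABELS:
        vals = df.loc[df["bin"] == label, "cis_share"].to_numpy()
        if vals.size == 0:
            continue
        row = {
            "bin": label,
            "n_genes": int(vals.size),
            "mean_cis_share": float(vals.mean()),
        }
        if n_boot > 0:
            idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
            means = vals[idx].mean(axis=1)
            row["ci_low"] = float(np.percentile(means, 2.5))
            row["ci_high"] = float(np.percentile(means, 97.5))
        else:
            row["ci_low"] = np.nan
            row["ci_high"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def loo_influence(records: pd.DataFrame) -> pd.DataFrame:
    """Leave-one-F1-out deltas of the overall log2 hybrid ratio.

    For each gene x tissue with >= 2 passing crosses, recompute the overall
    hybrid log2 ratio with each cross's counts removed; delta = full -
    dropped.  Genes with a single passing cross are omitted.
    """
    ok = records[records["complete"] & records["passes_depth"]]
    rows = []
    for (gid, tissue), sub in ok.groupby(["gene_id", "tissue"], sort=True):
        if len(sub) < 2:
            continue
        tot_m = sub["hybrid_m"].sum()
        tot_t = sub["hybrid_t"].sum()
        if tot_m <= 0 or tot_t <= 0:
            continue
        full = np.log2(tot_m / tot_t)
        for _, r in sub.iterrows():
            rm, rt = tot_m - r["hybrid_m"], tot_t - r["hybrid_t"]
            if rm <= 0 or rt <= 0:
                delta = np.nan
            else:
                delta = full - np.log2(rm / rt)
            rows.append(
                {
                    "gene_id": gid,
                    "tissue": tissue,
                    "cross": r["cross"],
                    "delta": delta,
                }
            )
    deltas = pd.DataFrame(rows, columns=["gene_id", "tissue", "cross", "delta"])
    return deltas


def loo_summary(deltas: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean |delta| and mean delta of the leave-one-out analysis."""
    if deltas.empty:
        return pd.DataFrame(
            columns=["gene_id", "tissue", "mean_abs_delta", "mean_delta", "n_crosses"]
        )
    return (
        deltas.groupby(["gene_id", "tissue"], as_index=False)
        .agg(
            mean_abs_delta=("delta", lambda d: np.nanmean(np.abs(d))),
            mean_delta=("delta", "mean"),
            n_crosses=("cross", "size"),
        )
        .sort_values(["tissue", "gene_id"], kind="mergesort")
        .reset_index(drop=True)
    )
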