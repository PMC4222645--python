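"""Maize:teosinte expression ratios from allele-specific counts.

Pools replicates, corrects parent library sizes, and computes per-cross and
overall log2 ratios with a depth filter.  The hybrid log2 ratio is the cis
effect; the parent log2 ratio is cis + trans; their difference estimates the
trans effect.

Zero counts leave log ratios undefined (NaN): tests downstream operate on
the counts themselves, so such records keep their counts but are excluded
from effect-size summaries.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .simulate import CrossDesign, hybrid_name

logger = logging.getLogger(__name__)

DEFAULT_MIN_DEPTH = 100


def pool_replicates(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum allele counts over replicates per (gene, tissue, genotype)."""
    pooled = (
        counts.groupby(["gene_id", "tissue", "genotype"], as_index=False, sort=True)[
            ["maize_count", "teosinte_count"]
        ].sum()
    )
    return pooled


def library_sizes(pooled: pd.DataFrame) -> pd.DataFrame:
    """Total allele-informative reads per (tissue, genotype)."""
    lib = pooled.groupby(["tissue", "genotype"], as_index=False)[
        ["maize_count", "teosinte_count"]
    ].sum()
    lib["libsize"] = lib["maize_count"] + lib["teosinte_count"]
    return lib[["tissue", "genotype", "libsize"]]


def correct_parent_libsize(parent_m_raw, parent_t_raw, L_m: float, L_t: float):
    """Scale the larger-library parent's counts down to the smaller library.

    Scaling down (never up) keeps the binomial tests on corrected counts
    conservative.  Counts are rounded half-to-even back to integers.
    """
    if L_m <= 0 or L_t <= 0:
        raise ValueError("library sizes must be positive")
    m = np.asarray(parent_m_raw, dtype=float)
    t = np.asarray(parent_t_raw, dtype=float)
    if L_m > L_t:
        m = np.round(m * (L_t / L_m))
    elif L_t > L_m:
        t = np.round(t * (L_m / L_t))
    return m.astype(np.int64), t.astype(np.int64)


def _log2_ratio(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((num > 0) & (den > 0), np.log2(num / den), np.nan)
    return out


def cross_ratios(
    pooled: pd.DataFrame,
    design: CrossDesign,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> pd.DataFrame:
    """Per gene x tissue x cross ratio records.

    ``passes_depth`` requires both the hybrid and the (library-corrected)
    parent comparison to reach ``min_depth``.  Crosses missing a genotype in
    a tissue are emitted with ``complete=False`` and excluded downstream.
    """
    lib = library_sizes(pooled).set_index(["tissue", "genotype"])["libsize"]
    # per-genotype gene -> counts lookup
    frames = []
    for tissue in design.tissues:
        sub = pooled[pooled["tissue"] == tissue]
        by_geno = {
            g: d.set_index("gene_id") for g, d in sub.groupby("genotype", sort=False)
        }
        genes = np.array(sorted(sub["gene_id"].unique()))
        for m_line, t_line in design.crosses:
            geno = hybrid_name(m_line, t_line)
            missing = [g for g in (geno, m_line, t_line) if g not in by_geno]
            if missing:
                logger.warning(
                    "tissue %s cross %s: missing genotype(s) %s; flagged incomplete",
                    tissue,
                    geno,
                    missing,
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "gene_id": genes,
                            "tissue": tissue,
                            "cross": geno,
                            "maize_line": m_line,
                            "teosinte_line": t_line,
                            "complete": False,
                            "passes_depth": False,
                        }
                    )
                )
                continue
            hyb = by_geno[geno].reindex(genes)
            par_m = by_geno[m_line].reindex(genes)
            par_t = by_geno[t_line].reindex(genes)
            hybrid_m = hyb["maize_count"].fillna(0).to_numpy(np.int64)
            hybrid_t = hyb["teosinte_count"].fillna(0).to_numpy(np.int64)
            pm_raw = par_m["maize_count"].fillna(0).to_numpy(np.int64)
            pt_raw = par_t["teosinte_count"].fillna(0).to_numpy(np.int64)
            L_m = float(lib.loc[(tissue, m_line)])
            L_t = float(lib.loc[(tissue, t_line)])
            pm, pt = correct_parent_libsize(pm_raw, pt_raw, L_m, L_t)
            log2_hybrid = _log2_ratio(hybrid_m, hybrid_t)
            log2_parent = _log2_ratio(pm, pt)
            depth_h = hybrid_m + hybrid_t
            depth_p = pm + pt
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": genes,
                        "tissue": tissue,
                        "cross": geno,
                        "maize_line": m_line,
                        "teosinte_line": t_line,
                        "complete": True,
                        "hybrid_m": hybrid_m,
                        "hybrid_t": hybrid_t,
                        "parent_m": pm,
                        "parent_t": pt,
                        "parent_m_raw": pm_raw,
                        "parent_t_raw": pt_raw,
                        "L_m": L_m,
                        "L_t": L_t,
                        "L_h": float(lib.loc[(tissue, geno)]),
                        "log2_hybrid": log2_hybrid,
                        "log2_parent": log2_parent,
                        "trans_effect": log2_parent - log2_hybrid,
                        "depth_hybrid": depth_h,
                        "depth_parent": depth_p,
                        "passes_depth": (depth_h >= min_depth)
                        & (depth_p >= min_depth),
                    }
                )
            )
    records = pd.concat(frames, ignore_index=True)
    records = records.sort_values(
        ["tissue", "gene_id", "cross"], kind="mergesort"
    ).reset_index(drop=True)
    return records


def overall_ratios(records: pd.DataFrame, design: CrossDesign) -> pd.DataFrame:
    """Overall per-gene ratios summed over passing crosses.

    Hybrid counts are plain sums.  On the parent side each inbred's raw
    per-gene count enters once (reads are never multiplied up by the number
    of crosses the inbred appears in), scaled to the smallest involved
    library.  Relative weights follow the number of passing crosses the
    inbred participates in for that gene, normalized so both sides carry
    the same total weight — the smaller side's line count, so counts are
    only ever scaled down and the binomial tests on the rounded weighted
    sums stay conservative.
    """
    ok = records[records["complete"] & records["passes_depth"]].copy()
    if ok.empty:
        return pd.DataFrame(
            columns=[
                "gene_id",
                "tissue",
                "sum_hybrid_m",
                "sum_hybrid_t",
                "wsum_parent_m",
                "wsum_parent_t",
                "n_crosses_used",
                "n_unique_maize",
                "n_unique_teosinte",
                "log2_hybrid_overall",
                "log2_parent_overall",
            ]
        )

    key = ["gene_id", "tissue"]
    hyb = ok.groupby(key, as_index=False).agg(
        sum_hybrid_m=("hybrid_m", "sum"),
        sum_hybrid_t=("hybrid_t", "sum"),
        n_crosses_used=("cross", "nunique"),
        n_unique_maize=("maize_line", "nunique"),
        n_unique_teosinte=("teosinte_line", "nunique"),
    )

    # smallest involved parent library per gene x tissue
    lref_m = ok.groupby(key)["L_m"].min()
    lref_t = ok.groupby(key)["L_t"].min()
    lref = pd.concat([lref_m, lref_t], axis=1).min(axis=1).rename("L_ref")

    def side(line_col, raw_col, lib_col, name):
        per_line = ok.groupby(key + [line_col], as_index=False).agg(
            raw=(raw_col, "first"), L=(lib_col, "first"), w=("cross", "size")
        )
        per_line = per_line.join(lref, on=key)
        per_line["scaled"] = per_line["raw"] * (per_line["L_ref"] / per_line["L"])
        return per_line.rename(columns={line_col: "line"}).assign(side=name)

    per_line = pd.concat(
        [
            side("maize_line", "parent_m_raw", "L_m", "m"),
            side("teosinte_line", "parent_t_raw", "L_t", "t"),
        ],
        ignore_index=True,
    )
    # total weight per gene and side = the smaller side's line count, so
    # every per-line weight stays <= its cross count and counts shrink
    side_tot = per_line.groupby(key + ["side"]).agg(
        wsum_raw=("w", "sum"), n_lines=("line", "nunique")
    )
    w_target = side_tot["n_lines"].groupby(level=key).min().rename("W")
    side_tot = side_tot.join(w_target, on=key)
    per_line = per_line.join(
        (side_tot["W"] / side_tot["wsum_raw"]).rename("w_scale"),
        on=key + ["side"],
    )
    per_line["contrib"] = per_line["w"] * per_line["w_scale"] * per_line["scaled"]
    sums = per_line.pivot_table(
        index=key, columns="side", values="contrib", aggfunc="sum"
    )
    par = pd.DataFrame(index=sums.index)
    par["wsum_parent_m"] = np.round(sums["m"]).astype(np.int64)
    par["wsum_parent_t"] = np.round(sums["t"]).astype(np.int64)

    out = hyb.merge(
        par[["wsum_parent_m", "wsum_parent_t"]].reset_index(), on=key, how="left"
    )
    out["log2_hybrid_overall"] = _log2_ratio(out["sum_hybrid_m"], out["sum_hybrid_t"])
    out["log2_parent_overall"] = _log2_ratio(
        out["wsum_parent_m"], out["wsum_parent_t"]
    )
    out = out.sort_values(["tissue", "gene_id"], kind="mergesort").reset_index(
        drop=True
    )
    return out
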