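"""Candidate gene lists with depth-weighted directional consistency tiers.

Genes whose overall cis effect is significant (cis-only or cis+trans; the
combined class is called CCT) are candidates for selection on expression.
To demand support from many independent crosses, genes must be assayed in
at least 15 F1s spanning at least 3 maize and 5 teosinte inbreds, and are
then tiered by the depth-weighted fraction of F1s whose hybrid ratio points
the same way: A = 100%, B = 90%, C = 80% consistency.  Analogous lists are
built for the cis-only and trans-only categories alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .classify import binom_test_1to1

COVERAGE_MIN_CROSSES = 15
COVERAGE_MIN_MAIZE = 3
COVERAGE_MIN_TEOSINTE = 5
TIER_THRESHOLDS = {"A": 1.0, "B": 0.9, "C": 0.8}

LIST_CATEGORIES = {
    "CCT": ("cis", "cis_plus_trans"),
    "cis_only": ("cis",),
    "trans_only": ("trans",),
}


def coverage_filter(
    n_crosses: int,
    n_unique_maize: int,
    n_unique_teosinte: int,
    min_crosses: int = COVERAGE_MIN_CROSSES,
    min_maize: int = COVERAGE_MIN_MAIZE,
    min_teosinte: int = COVERAGE_MIN_TEOSINTE,
) -> bool:
    """True iff the gene is backed by enough distinct crosses and parents."""
    return (
        n_crosses >= min_crosses
        and n_unique_maize >= min_maize
        and n_unique_teosinte >= min_teosinte
    )


def _tier(consistency: float) -> str:
    for name, thr in TIER_THRESHOLDS.items():
        if consistency >= thr:
            return name
    return "none"


def consistency_records(
    records: pd.DataFrame,
    min_crosses: int = COVERAGE_MIN_CROSSES,
    min_maize: int = COVERAGE_MIN_MAIZE,
    min_teosinte: int = COVERAGE_MIN_TEOSINTE,
) -> pd.DataFrame:
    """Depth-weighted directional consistency per gene x tissue.

    Direction per cross is the sign of the hybrid (cis) ratio, weighted by
    hybrid depth; crosses with exactly 1:1 hybrid counts contribute depth
    to the denominator only.  Only genes passing the coverage filter are
    returned.
    """
    ok = records[records["complete"] & records["passes_depth"]].copy()
    if ok.empty:
        return pd.DataFrame(
            columns=[
                "gene_id",
                "tissue",
                "n_crosses",
                "n_unique_maize",
                "n_unique_teosinte",
                "weighted_maize_fraction",
                "consistency",
                "tier",
                "favored_allele",
            ]
        )
    ok["maize_biased_depth"] = np.where(
        ok["hybrid_m"] > ok["hybrid_t"], ok["depth_hybrid"], 0
    )
    ok["teosinte_biased_depth"] = np.where(
        ok["hybrid_t"] > ok["hybrid_m"], ok["depth_hybrid"], 0
    )
    g = ok.groupby(["gene_id", "tissue"], as_index=False).agg(
        n_crosses=("cross", "nunique"),
        n_unique_maize=("maize_line", "nunique"),
        n_unique_teosinte=("teosinte_line", "nunique"),
        depth_maize=("maize_biased_depth", "sum"),
        depth_teosinte=("teosinte_biased_depth", "sum"),
        depth_total=("depth_hybrid", "sum"),
    )
    covered = g[
        (g["n_crosses"] >= min_crosses)
        & (g["n_unique_maize"] >= min_maize)
        & (g["n_unique_teosinte"] >= min_teosinte)
    ].copy()
    if (covered["depth_total"] <= 0).any():
        raise ValueError("zero total hybrid depth for a covered gene")
    covered["weighted_maize_fraction"] = (
        covered["depth_maize"] / covered["depth_total"]
    )
    wt = covered["depth_teosinte"] / covered["depth_total"]
    covered["consistency"] = np.maximum(covered["weighted_maize_fraction"], wt)
    covered["tier"] = covered["consistency"].map(_tier)
    covered["favored_allele"] = np.where(
        covered["weighted_maize_fraction"] >= wt, "maize", "teosinte"
    )
    cols = [
        "gene_id",
        "tissue",
        "n_crosses",
        "n_unique_maize",
        "n_unique_teosinte",
        "weighted_maize_fraction",
        "consistency",
        "tier",
        "favored_allele",
    ]
    return covered[cols].sort_values(
        ["tissue", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)


def build_lists(
    calls: pd.DataFrame, consistency: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tissue list membership and cross-tissue union membership.

    Returns ``(membership, union)``.  ``membership`` has one row per
    (gene, tissue, list_class) for genes in a tier (A/B/C); ``union`` marks
    a gene as a member of a list class at a tier level if it qualifies in
    at least one tissue (tier levels are cumulative: A, AB, ABC).
    """
    merged = consistency.merge(
        calls[["gene_id", "tissue", "category"]], on=["gene_id", "tissue"]
    )
    rows = []
    for list_class, cats in LIST_CATEGORIES.items():
        sub = merged[merged["category"].isin(cats) & (merged["tier"] != "none")]
        for _, r in sub.iterrows():
            rows.append(
                {
                    "gene_id": r["gene_id"],
                    "tissue": r["tissue"],
                    "list_class": list_class,
                    "tier": r["tier"],
                    "favored_allele": r["favored_allele"],
                    "weighted_maize_fraction": r["weighted_maize_fraction"],
                }
            )
    membership = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "tissue",
            "list_class",
            "tier",
            "favored_allele",
            "weighted_maize_fraction",
        ],
    )
    if not membership.empty:
        membership = membership.sort_values(
            ["list_class", "tissue", "gene_id"], kind="mergesort"
        ).reset_index(drop=True)

    union_rows = []
    tier_levels = {"A": ("A",), "AB": ("A", "B"), "ABC": ("A", "B", "C")}
    for list_class in LIST_CATEGORIES:
        sub = membership[membership["list_class"] == list_class]
        for level, tiers in tier_levels.items():
            genes = sorted(sub[sub["tier"].isin(tiers)]["gene_id"].unique())
            for gid in genes:
                union_rows.append(
                    {"gene_id": gid, "list_class": list_class, "tier_level": level}
                )
    union = pd.DataFrame(
        union_rows, columns=["gene_id", "list_class", "tier_level"]
    )
    return membership, union


def venn_counts(membership: pd.DataFrame, tissues) -> pd.DataFrame:
    """Count genes per tissue combination, per list class."""
    rows = []
    for list_class, sub in membership.groupby("list_class"):
        per_gene = sub.groupby("gene_id")["tissue"].agg(frozenset)
        combos = per_gene.value_counts()
        for combo, n in combos.items():
            rows.append(
                {
                    "list_class": list_class,
                    "tissues": "+".join(sorted(combo)),
                    "n_genes": int(n),
                }
            )
    return pd.DataFrame(rows, columns=["list_class", "tissues", "n_genes"])


def directional_bias_test(membership: pd.DataFrame) -> dict:
    """Maize- vs teosinte-favored counts and a two-sided binomial p."""
    if membership.empty:
        raise ValueError("empty candidate list")
    n_maize = int((membership["favored_allele"] == "maize").sum())
    n_teosinte = int((membership["favored_allele"] == "teosinte").sum())
    p = binom_test_1to1(n_maize, n_teosinte)
    return {"n_maize_biased": n_maize, "n_teosinte_biased": n_teosinte, "p": p}


def reference_bias_check(
    records: pd.DataFrame,
    genes,
    reference_line: str = "B73",
) -> dict:
    """Test whether maize-allele bias is stronger in reference-line crosses.

    Per gene, the bias direction is computed separately from the pooled
    hybrid counts of crosses involving ``reference_line`` and of the
    remaining crosses; a 2x2 Fisher's exact test compares the two
    direction tallies.  A systematic reference-alignment artifact would
    inflate maize bias specifically in the reference crosses.
    """
    ok = records[
        records["complete"]
        & records["passes_depth"]
        & records["gene_id"].isin(set(genes))
    ].copy()
    is_ref = ok["maize_line"] == reference_line
    if not is_ref.any():
        raise ValueError(f"no crosses involve reference line {reference_line}")

    def tally(sub):
        g = sub.groupby("gene_id")[["hybrid_m", "hybrid_t"]].sum()
        maize = int((g["hybrid_m"] > g["hybrid_t"]).sum())
        teo = int((g["hybrid_t"] > g["hybrid_m"]).sum())
        return teo, maize

    ref_t, ref_m = tally(ok[is_ref])
    non_t, non_m = tally(ok[~is_ref])
    table = [[ref_t, ref_m], [non_t, non_m]]
    p = float(stats.fisher_exact(np.array(table), alternative="two-sided")[1])
    return {"table": table, "p": p}
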