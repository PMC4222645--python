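"""Cis/trans regulatory classification of genes from overall ratio records.

Three tests per gene: an exact two-sided binomial test of the parent
maize:teosinte counts against 1:1 (cis + trans), the same test on the
hybrid allele counts (pure cis), and — only for genes where at least one
binomial test is significant — a two-sided Fisher's exact test comparing
the parent and hybrid ratios (trans).  False discovery is controlled per
test family within tissue with Storey q-values at 0.5% by default, and the
three significance flags plus effect signs place each gene in one of seven
regulatory categories:

==============  =========  =========  =====  ================
category        parent BT  hybrid BT  FET    effect signs
==============  =========  =========  =====  ================
cis             sig        sig        ns     --
trans           sig        ns         sig    --
cis_plus_trans  sig        sig        sig    same direction
cis_x_trans     sig        sig        sig    opposite
compensatory    ns         sig        sig    --
conserved       ns         ns         (not run)
ambiguous       any other pattern
==============  =========  =========  =====  ================
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FDR = 0.005

CATEGORIES = (
    "cis",
    "trans",
    "cis_plus_trans",
    "cis_x_trans",
    "compensatory",
    "conserved",
    "ambiguous",
)


def binom_test_1to1(m: int, t: int) -> float:
    """Exact two-sided binomial p-value against a 1:1 allele ratio.

    Uses the minimum-likelihood definition (sum of outcome probabilities
    <= that of the observed outcome), which for p=0.5 reduces to twice the
    smaller tail by symmetry.
    """
    n = m + t
    if n < 1:
        raise ValueError("need at least one read")
    kmin = min(m, t)
    return float(min(1.0, 2.0 * stats.binom.cdf(kmin, n, 0.5)))


def binom_test_1to1_vec(m, t):
    """Vectorized :func:`binom_test_1to1`."""
    m = np.asarray(m, dtype=np.int64)
    t = np.asarray(t, dtype=np.int64)
    n = m + t
    if np.any(n < 1):
        raise ValueError("need at least one read per gene")
    kmin = np.minimum(m, t)
    return np.minimum(1.0, 2.0 * stats.binom.cdf(kmin, n, 0.5))


def fet_parent_vs_hybrid(
    parent_m: int, parent_t: int, hybrid_m: int, hybrid_t: int
) -> float:
    """Two-sided Fisher's exact p on [[parent_m, parent_t], [hybrid_m, hybrid_t]].

    Two-sidedness sums tables with probability <= the observed table's.
    A degenerate table (a zero row and a zero column) has p = 1.
    """
    table = np.array([[parent_m, parent_t], [hybrid_m, hybrid_t]], dtype=np.int64)
    if table.min() < 0:
        raise ValueError("counts must be non-negative")
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def storey_qvalues(p, lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values with pi0 estimated at a single fixed lambda.

    pi0 = mean(p > lambda) / (1 - lambda), clamped into (0, 1] (an estimate
    of exactly zero is floored at 1/m so q-values stay positive);
    q_i = min over p_j >= p_i of pi0 * m * p_j / rank(p_j), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = np.mean(p > lambda_) / (1.0 - lambda_)
    pi0 = min(pi0, 1.0)
    if pi0 <= 0.0:
        pi0 = 1.0 / m
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def classify_gene(
    sig_parent: bool,
    sig_hybrid: bool,
    sig_fet: bool,
    cis_sign: int = 0,
    trans_sign: int = 0,
) -> str:
    """Map the three significance flags (and signs) to a category.

    A sign of 0 (exact equality) is grouped with "same direction".  Genes
    with both binomial tests non-significant are conserved regardless of
    any FET result (the FET is not run for them).
    """
    if not sig_parent and not sig_hybrid:
        return "conserved"
    if sig_parent and sig_hybrid and not sig_fet:
        return "cis"
    if sig_parent and not sig_hybrid and sig_fet:
        return "trans"
    if sig_parent and sig_hybrid and sig_fet:
        opposite = cis_sign * trans_sign < 0
        return "cis_x_trans" if opposite else "cis_plus_trans"
    if not sig_parent and sig_hybrid and sig_fet:
        return "compensatory"
    return "ambiguous"


def _sign_with_pseudocount(num, den):
    """Sign of log2((num+.5)/(den+.5)): robust to zero counts."""
    return np.sign(np.asarray(num, float) - np.asarray(den, float)).astype(int)


def classify_all(
    overall: pd.DataFrame, fdr: float = DEFAULT_FDR
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full test battery per tissue and categorize every gene.

    Returns ``(calls, summary)``: per-gene calls with p/q-values and
    category, and per-tissue category counts and proportions.
    """
    calls = []
    for tissue, sub in overall.groupby("tissue", sort=True):
        sub = sub.reset_index(drop=True)
        p_hyb = binom_test_1to1_vec(sub["sum_hybrid_m"], sub["sum_hybrid_t"])
        p_par = binom_test_1to1_vec(sub["wsum_parent_m"], sub["wsum_parent_t"])
        q_hyb = storey_qvalues(p_hyb)
        q_par = storey_qvalues(p_par)
        sig_hyb = q_hyb < fdr
        sig_par = q_par < fdr

        # FET only where at least one binomial test rejects 1:1
        do_fet = sig_hyb | sig_par
        p_fet = np.full(len(sub), np.nan)
        idx = np.flatnonzero(do_fet)
        for i in idx:
            p_fet[i] = fet_parent_vs_hybrid(
                int(sub.at[i, "wsum_parent_m"]),
                int(sub.at[i, "wsum_parent_t"]),
                int(sub.at[i, "sum_hybrid_m"]),
                int(sub.at[i, "sum_hybrid_t"]),
            )
        q_fet = np.full(len(sub), np.nan)
        if idx.size:
            q_fet[idx] = storey_qvalues(p_fet[idx])
        sig_fet = np.where(np.isnan(q_fet), False, q_fet < fdr)

        cis_sign = _sign_with_pseudocount(sub["sum_hybrid_m"], sub["sum_hybrid_t"])
        # trans sign: parent ratio relative to hybrid ratio, on pseudocounted logs
        lp = np.log2((sub["wsum_parent_m"] + 0.5) / (sub["wsum_parent_t"] + 0.5))
        lh = np.log2((sub["sum_hybrid_m"] + 0.5) / (sub["sum_hybrid_t"] + 0.5))
        trans_sign = np.sign(lp - lh).astype(int)

        category = [
            classify_gene(sp, sh, sf, cs, ts)
            for sp, sh, sf, cs, ts in zip(
                sig_par, sig_hyb, sig_fet, cis_sign, trans_sign
            )
        ]
        calls.append(
            pd.DataFrame(
                {
                    "gene_id": sub["gene_id"],
                    "tissue": tissue,
                    "p_parent_bt": p_par,
                    "p_hybrid_bt": p_hyb,
                    "p_fet": p_fet,
                    "q_parent_bt": q_par,
                    "q_hybrid_bt": q_hyb,
                    "q_fet": q_fet,
                    "sig_parent": sig_par,
                    "sig_hybrid": sig_hyb,
                    "sig_fet": sig_fet,
                    "cis_sign": cis_sign,
                    "trans_sign": trans_sign,
                    "category": category,
                }
            )
        )
    calls_df = pd.concat(calls, ignore_index=True)
    calls_df = calls_df.sort_values(
        ["tissue", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)

    rows = []
    for tissue, sub in calls_df.groupby("tissue", sort=True):
        n = len(sub)
        counts = sub["category"].value_counts()
        for cat in CATEGORIES:
            c = int(counts.get(cat, 0))
            rows.append(
                {
                    "tissue": tissue,
                    "category": cat,
                    "n_genes": c,
                    "proportion": c / n if n else np.nan,
                }
            )
    summary = pd.DataFrame(rows)
    return calls_df, summary
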