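"""Additive and dominant inheritance of expression in F1 hybrids.

For each gene and cross, with library-normalized expression totals P_M
(maize parent, diploid), P_T (teosinte parent) and F1 (both alleles of the
hybrid): the additive effect is a = (P_M - P_T)/2, the midparent is
(P_M + P_T)/2, the dominance effect is d = F1 - midparent, and the
dominance ratio is D/A = d/|a|.  With this convention D/A = +1 means the
F1 matches the higher-expressing parent regardless of which species that
is.  Per-gene outlying D/A values across crosses are removed by iterating
Dixon's Q test before averaging.  |D/A| < 0.25 is called additive and
0.75 < |D/A| < 1.25 dominant, with the dominant allele mapped back to the
species of the matched parent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .classify import binom_test_1to1

ADDITIVE_MAX = 0.25
DOMINANT_LOW = 0.75
DOMINANT_HIGH = 1.25
DIXON_ALPHA = 0.05

# Two-sided Dixon critical values at alpha = 0.05 (95% confidence),
# staged r statistics: r10 for n<=7, r11 for 8<=n<=10, r21 for 11<=n<=13,
# r22 for n>=14 (Rorabacher's recomputed tables).
DIXON_Q95 = {
    3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568,
    8: 0.608, 9: 0.564, 10: 0.530,
    11: 0.619, 12: 0.583, 13: 0.557,
    14: 0.586, 15: 0.565, 16: 0.546, 17: 0.529, 18: 0.514, 19: 0.501,
    20: 0.489, 21: 0.478, 22: 0.468, 23: 0.459, 24: 0.451, 25: 0.443,
    26: 0.436, 27: 0.429, 28: 0.423, 29: 0.417, 30: 0.412,
}


def cross_da(p_m_total: float, p_t_total: float, f1_total: float) -> tuple:
    """Additive effect, dominance effect, and D/A for one cross.

    Returns ``(a, d, da)``; ``da`` is NaN when a = 0 (no additive
    difference to scale by).
    """
    a = (p_m_total - p_t_total) / 2.0
    d = f1_total - (p_m_total + p_t_total) / 2.0
    da = d / abs(a) if a != 0 else np.nan
    return a, d, da


def _dixon_q(x: np.ndarray) -> tuple[float, int]:
    """Dixon's staged Q statistic for the more extreme end of sorted x.

    Returns (Q, index-of-suspect) where index is 0 (low end) or n-1.
    """
    n = x.size
    if n <= 7:
        i, j = 1, n - 1  # r10: gap to nearest, range to far end
    elif n <= 10:
        i, j = 1, n - 2  # r11
    elif n <= 13:
        i, j = 2, n - 2  # r21
    else:
        i, j = 2, n - 3  # r22
    span_hi = x[n - 1] - x[n - 1 - j]
    span_lo = x[j] - x[0]
    q_hi = (x[n - 1] - x[n - 1 - i]) / span_hi if span_hi > 0 else 0.0
    q_lo = (x[i] - x[0]) / span_lo if span_lo > 0 else 0.0
    if q_hi >= q_lo:
        return q_hi, n - 1
    return q_lo, 0


def dixon_filter(values, alpha: float = DIXON_ALPHA) -> tuple[np.ndarray, int]:
    """Iteratively remove Dixon outliers; returns (retained, n_removed).

    Vectors shorter than 3 are returned unchanged; iteration never reduces
    the sample below 3.  Critical values are tabulated for n up to 30;
    larger samples use the n = 30 value (conservative toward removal of
    only gross outliers).
    """
    if alpha != DIXON_ALPHA:
        raise ValueError("only the embedded alpha = 0.05 table is available")
    x = np.sort(np.asarray(values, dtype=float))
    x = x[np.isfinite(x)]
    removed = 0
    while x.size > 3:
        q, idx = _dixon_q(x)
        crit = DIXON_Q95.get(int(x.size), DIXON_Q95[30])
        if q > crit:
            x = np.delete(x, idx)
            removed += 1
        else:
            break
    return x, removed


def classify_inheritance(overall_da: float, a_sign: int) -> tuple[str, str]:
    """Inheritance class and dominant allele from the mean D/A.

    D/A near +1: the F1 matches the higher parent, so the higher parent's
    allele is dominant (maize if a > 0 else teosinte); near -1 the lower
    parent's allele is dominant.
    """
    if not np.isfinite(overall_da):
        return "undefined", "none"
    ada = abs(overall_da)
    if ada < ADDITIVE_MAX:
        return "additive", "none"
    if DOMINANT_LOW < ada < DOMINANT_HIGH:
        if a_sign == 0:
            return "dominant", "none"
        high_parent = "maize" if a_sign > 0 else "teosinte"
        low_parent = "teosinte" if a_sign > 0 else "maize"
        return "dominant", high_parent if overall_da > 0 else low_parent
    return "other", "none"


def gene_dominance(records: pd.DataFrame, alpha: float = DIXON_ALPHA) -> pd.DataFrame:
    """Per-gene dominance from passing per-cross records.

    Expression totals are normalized to a common per-tissue scale: each
    genotype's counts are divided by its library size and multiplied by
    the tissue-mean library, so parent and hybrid totals are comparable.
    """
    ok = records[records["complete"] & records["passes_depth"]].copy()
    if ok.empty:
        return pd.DataFrame(
            columns=[
                "gene_id",
                "tissue",
                "overall_da",
                "n_crosses",
                "n_outliers_removed",
                "inheritance_class",
                "dominant_allele",
            ]
        )
    lbar = ok.groupby("tissue")[["L_m", "L_t", "L_h"]].transform("mean").mean(axis=1)
    p_m = ok["parent_m_raw"] / ok["L_m"] * lbar
    p_t = ok["parent_t_raw"] / ok["L_t"] * lbar
    f1 = (ok["hybrid_m"] + ok["hybrid_t"]) / ok["L_h"] * lbar
    ok["a"] = (p_m - p_t) / 2.0
    ok["d"] = f1 - (p_m + p_t) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ok["da"] = np.where(ok["a"] != 0, ok["d"] / ok["a"].abs(), np.nan)

    rows = []
    for (gid, tissue), sub in ok.groupby(["gene_id", "tissue"], sort=True):
        da = sub["da"].to_numpy()
        da = da[np.isfinite(da)]
        if da.size == 0:
            continue
        retained, removed = dixon_filter(da, alpha=alpha)
        overall_da = float(retained.mean())
        a_sign = int(np.sign(sub["a"].mean()))
        klass, allele = classify_inheritance(overall_da, a_sign)
        rows.append(
            {
                "gene_id": gid,
                "tissue": tissue,
                "overall_da": overall_da,
                "n_crosses": int(da.size),
                "n_outliers_removed": removed,
                "inheritance_class": klass,
                "dominant_allele": allele,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "tissue",
            "overall_da",
            "n_crosses",
            "n_outliers_removed",
            "inheritance_class",
            "dominant_allele",
        ],
    )


def dominance_summary(
    dominance: pd.DataFrame, cis_only_genes, trans_only_genes
) -> dict:
    """Compare dominance rates between cis-only and trans-only lists.

    2x2 Fisher's exact test on {cis-only, trans-only} x {dominant,
    additive}, plus a two-sided binomial test of maize- vs teosinte-
    dominant counts among trans-only genes.
    """
    cis = dominance[dominance["gene_id"].isin(set(cis_only_genes))]
    trans = dominance[dominance["gene_id"].isin(set(trans_only_genes))]
    if cis.empty or trans.empty:
        raise ValueError("both candidate lists must be non-empty")

    def tab(sub):
        dom = int((sub["inheritance_class"] == "dominant").sum())
        add = int((sub["inheritance_class"] == "additive").sum())
        return dom, add

    cis_dom, cis_add = tab(cis)
    trans_dom, trans_add = tab(trans)
    table = [[cis_dom, cis_add], [trans_dom, trans_add]]
    fet_p = float(stats.fisher_exact(np.array(table))[1])

    tr_dom = trans[trans["inheritance_class"] == "dominant"]
    n_maize = int((tr_dom["dominant_allele"] == "maize").sum())
    n_teo = int((tr_dom["dominant_allele"] == "teosinte").sum())
    binom_p = binom_test_1to1(n_maize, n_teo) if (n_maize + n_teo) else np.nan
    return {
        "table": table,
        "fet_p": fet_p,
        "cis_dominant_rate": cis_dom / len(cis),
        "trans_dominant_rate": trans_dom / len(trans),
        "trans_maize_dominant": n_maize,
        "trans_teosinte_dominant": n_teo,
        "binom_p": binom_p,
    }
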