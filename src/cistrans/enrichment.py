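"""Gene-set enrichment of candidate lists against external annotations.

Generic 2x2 Fisher's exact overlap tests (with the product-formula
expected count), enrichment of candidates within QTL support intervals,
comparison of selection-scan (XPCLR) score distributions between candidate
and conserved genes, agreement between allelic expression direction and
differential methylation, and standard multiple-testing corrections.
External annotations (selection candidates, QTL interval membership,
XPCLR scores, DMR-neighbor genes) are consumed as inputs, never computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSet:
    """A named set of genes with optional per-gene score or direction."""

    name: str
    members: frozenset[str]
    scores: dict[str, float] = field(default_factory=dict)
    directions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)


def set_overlap_fet(
    list_genes, set_genes, universe, sided: str = "greater"
) -> dict:
    """Fisher's exact overlap test of a candidate list against a gene set.

    The 2x2 table is [[in both, list only], [set only, neither]] within
    ``universe``; the expected overlap is |list| * |set| / |universe|.
    ``sided="greater"`` is the one-tailed enrichment test; ``"two-sided"``
    tests enrichment or depletion.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    lset = set(list_genes) & universe
    sset = set(set_genes) & universe
    both = len(lset & sset)
    table = np.array(
        [
            [both, len(lset) - both],
            [len(sset) - both, len(universe) - len(lset) - len(sset) + both],
        ]
    )
    odds, p = stats.fisher_exact(table, alternative=sided)
    expected = len(lset) * len(sset) / len(universe)
    return {
        "universe": len(universe),
        "list_size": len(lset),
        "set_size": len(sset),
        "observed": both,
        "expected": expected,
        "odds_ratio": float(odds),
        "p": float(p),
    }


def xpclr_compare(scores_candidates, scores_conserved) -> dict:
    """Compare selection-score distributions of candidate vs conserved genes.

    Natural-log transforms the (positive) scores, then runs a two-sample
    Kolmogorov-Smirnov test (shape) and a Welch t-test (mean).  Non-positive
    scores are excluded with a warning.
    """
    out = []
    for name, scores in (
        ("candidates", scores_candidates),
        ("conserved", scores_conserved),
    ):
        s = np.asarray(list(scores), dtype=float)
        bad = ~(s > 0)
        if bad.any():
            logger.warning("%d non-positive %s scores excluded", bad.sum(), name)
        s = np.log(s[~bad])
        if s.size < 2:
            raise ValueError(f"need >= 2 positive scores in {name}")
        out.append(s)
    a, b = out
    ks = stats.ks_2samp(a, b, method="asymp")
    tt = stats.ttest_ind(a, b, equal_var=False)
    t_p = float(tt.pvalue)
    if np.isnan(t_p) and np.allclose(a.mean(), b.mean()):
        t_p = 1.0  # zero-variance identical groups
    return {
        "ks_p": float(ks.pvalue),
        "t_p": t_p,
        "mean_ln_candidates": float(a.mean()),
        "mean_ln_conserved": float(b.mean()),
    }


def qtl_enrichment(
    list_genes,
    qtl: pd.DataFrame,
    universe,
    max_genes: int = 20,
    sided: str = "greater",
) -> pd.DataFrame:
    """Per-trait enrichment of candidates among QTL support-interval genes.

    ``qtl`` columns: trait, qtl_id, gene.  Intervals with more than
    ``max_genes`` member genes are dropped before the per-trait test of
    the list against the union of surviving interval genes; Bonferroni
    corrects over traits.
    """
    sizes = qtl.groupby(["trait", "qtl_id"])["gene"].nunique()
    keep = sizes[sizes <= max_genes].reset_index()[["trait", "qtl_id"]]
    surviving = qtl.merge(keep, on=["trait", "qtl_id"])
    rows = []
    for trait in sorted(qtl["trait"].unique()):
        genes = set(surviving.loc[surviving["trait"] == trait, "gene"])
        if not genes:
            logger.warning("trait %s: no QTL interval with <= %d genes", trait, max_genes)
            continue
        res = set_overlap_fet(list_genes, genes, universe, sided=sided)
        res["trait"] = trait
        rows.append(res)
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_bonferroni"] = p_adjust(df["p"].to_numpy(), method="bonferroni")
    return df


def dmr_agreement(
    favored_allele: dict,
    hypomethylated_allele: dict,
    list_genes,
    universe,
) -> dict:
    """Concordance of allele expression bias with methylation direction.

    Agreement is the fraction of intersected genes whose higher-expressed
    allele is the hypomethylated one (hypomethylation is permissive for
    expression), plus an overlap FET of the candidate list against the
    DMR-neighbor gene set.
    """
    dmr_genes = set(hypomethylated_allele)
    fet = set_overlap_fet(list_genes, dmr_genes, universe)
    common = [g for g in list_genes if g in hypomethylated_allele and g in favored_allele]
    if not common:
        return {"agreement": np.nan, "n_compared": 0, "overlap_fet": fet}
    agree = sum(
        favored_allele[g] == hypomethylated_allele[g] for g in common
    ) / len(common)
    return {"agreement": agree, "n_compared": len(common), "overlap_fet": fet}


def p_adjust(pvec, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg or Bonferroni adjusted p-values."""
    p = np.asarray(pvec, dtype=float)
    if p.size == 0:
        return p
    if method == "BH":
        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return multipletests(p, method="bonferroni")[1]
    raise ValueError(f"unknown method {method!r}")


def read_gene_sets(path) -> dict[str, GeneSet]:
    """Read two-column TSV (set name, gene) into GeneSet objects."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set", "gene"], dtype=str)
    return {
        name: GeneSet(name=name, members=frozenset(sub["gene"]))
        for name, sub in df.groupby("set")
    }


def read_scores(path) -> dict[str, float]:
    """Read per-gene score TSV (gene, score) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
    return dict(zip(df["gene"].astype(str), df["score"].astype(float)))
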