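"""Dominance: D/A ratios, iterative Dixon filtering, inheritance calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cistrans.dominance import (
    DIXON_Q95,
    classify_inheritance,
    cross_da,
    dixon_filter,
    dominance_summary,
    gene_dominance,
)


class TestCrossDA:
    def test_additive_worked_example(self):
        # CRE disruption halves per-allele output: progenitor parent 10
        # reads, crop parent 2, F1 6 (5 + 1) -> purely additive
        a, d, da = cross_da(10, 2, 6)
        assert (a, d, da) == (4.0, 0.0, 0.0)
        assert classify_inheritance(da, int(np.sign(a)))[0] == "additive"

    def test_complete_dominance_toward_maize(self):
        a, d, da = cross_da(10, 2, 10)
        assert (a, d, da) == (4.0, 4.0, 1.0)
        klass, allele = classify_inheritance(da, int(np.sign(a)))
        assert (klass, allele) == ("dominant", "maize")

    def test_complete_dominance_toward_teosinte(self):
        # F1 matches the higher (teosinte) parent: with da = d/|a| the
        # ratio is +1 and the dominant allele maps to the higher parent
        a, d, da = cross_da(2, 10, 10)
        assert a == -4.0 and d == 4.0 and da == 1.0
        klass, allele = classify_inheritance(da, int(np.sign(a)))
        assert (klass, allele) == ("dominant", "teosinte")

    def test_low_parent_dominance(self):
        # F1 matches the lower parent: da = -1, low parent's allele dominant
        a, d, da = cross_da(10, 2, 2)
        assert da == -1.0
        klass, allele = classify_inheritance(da, 1)
        assert (klass, allele) == ("dominant", "teosinte")

    def test_no_additive_difference_undefined(self):
        _, _, da = cross_da(5, 5, 8)
        assert np.isnan(da)

    @given(
        pm=st.floats(0.1, 1e4),
        pt=st.floats(0.1, 1e4),
        f1=st.floats(0.1, 1e4),
        scale=st.floats(0.01, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_da_scale_invariant(self, pm, pt, f1, scale):
        _, _, da1 = cross_da(pm, pt, f1)
        _, _, da2 = cross_da(pm * scale, pt * scale, f1 * scale)
        if np.isfinite(da1):
            assert da2 == pytest.approx(da1, rel=1e-9)


class TestDixonFilter:
    def test_single_gross_outlier_removed(self):
        vals = [0.10, 0.11, 0.12, 0.95]
        q = (0.95 - 0.12) / (0.95 - 0.10)
        assert q > DIXON_Q95[4]
        retained, removed = dixon_filter(vals)
        assert removed == 1
        assert 0.95 not in retained
        assert sorted(retained) == [0.10, 0.11, 0.12]

    def test_identical_values_untouched(self):
        retained, removed = dixon_filter([0.5] * 8)
        assert removed == 0
        assert len(retained) == 8

    def test_low_end_outlier_removed(self):
        retained, removed = dixon_filter([-5.0, 0.50, 0.52, 0.54, 0.56])
        assert removed == 1
        assert -5.0 not in retained

    def test_never_below_three_values(self):
        retained, _ = dixon_filter([0.0, 100.0, 200.0, 300.0])
        assert len(retained) >= 3

    def test_short_vectors_unfiltered(self):
        retained, removed = dixon_filter([0.0, 50.0])
        assert removed == 0 and len(retained) == 2

    def test_exchangeable_values_rarely_trimmed(self):
        # with well-behaved D/A vectors the filter removes at most a
        # couple of values for the vast majority of genes
        rng = np.random.default_rng(0)
        removed_counts = []
        for _ in range(300):
            vals = rng.normal(0.0, 0.3, size=20)
            _, removed = dixon_filter(vals)
            removed_counts.append(removed)
        assert np.mean(np.array(removed_counts) <= 2) > 0.9

    def test_unsupported_alpha_rejected(self):
        with pytest.raises(ValueError):
            dixon_filter([1.0, 2.0, 3.0, 4.0], alpha=0.01)


class TestClassifyInheritance:
    @pytest.mark.parametrize(
        "da,a_sign,klass",
        [
            (0.0, 1, "additive"),
            (0.24, 1, "additive"),
            (0.5, 1, "other"),
            (1.0, 1, "dominant"),
            (-0.9, 1, "dominant"),
            (1.3, 1, "other"),
            (np.nan, 1, "undefined"),
        ],
    )
    def test_thresholds(self, da, a_sign, klass):
        assert classify_inheritance(da, a_sign)[0] == klass


def _records_for_dominance(gene_specs):
    """Build per-cross records with equal libraries for dominance tests.

    gene_specs: {gene: list of (pm_raw, pt_raw, hm, ht)} per cross.
    """
    rows = []
    for gene, crosses in gene_specs.items():
        for i, (pm, pt, hm, ht) in enumerate(crosses):
            rows.append(
                {
                    "gene_id": gene,
                    "tissue": "ear",
                    "cross": f"M{i}xT{i}",
                    "maize_line": f"M{i}",
                    "teosinte_line": f"T{i}",
                    "complete": True,
                    "passes_depth": True,
                    "parent_m_raw": pm,
                    "parent_t_raw": pt,
                    "hybrid_m": hm,
                    "hybrid_t": ht,
                    "L_m": 1e6,
                    "L_t": 1e6,
                    "L_h": 1e6,
                }
            )
    return pd.DataFrame(rows)


class TestGeneDominance:
    def test_pure_additive_construction(self):
        # F1 allele totals equal per-allele parental halves -> d = 0 exactly
        rec = _records_for_dominance(
            {"g1": [(1000, 200, 500, 100)] * 4}
        )
        out = gene_dominance(rec)
        assert out.loc[0, "overall_da"] == 0.0
        assert out.loc[0, "inheritance_class"] == "additive"
        assert out.loc[0, "dominant_allele"] == "none"

    def test_maize_dominant_gene(self):
        rec = _records_for_dominance(
            {"g1": [(1000, 200, 500, 500)] * 4}
        )
        out = gene_dominance(rec)
        assert out.loc[0, "overall_da"] == pytest.approx(1.0)
        assert out.loc[0, "inheritance_class"] == "dominant"
        assert out.loc[0, "dominant_allele"] == "maize"

    def test_outlier_cross_excluded(self):
        crosses = [(1000, 200, 500, 100)] * 5 + [(1000, 200, 1400, 1400)]
        rec = _records_for_dominance({"g1": crosses})
        out = gene_dominance(rec)
        assert out.loc[0, "n_outliers_removed"] == 1
        assert out.loc[0, "overall_da"] == pytest.approx(0.0)

    def test_summary_separates_planted_classes(self):
        # trans-only genes planted with complete dominance, cis-only additive
        specs = {}
        for i in range(12):
            specs[f"cis{i}"] = [(1000, 200, 500, 100)] * 4
            specs[f"trans{i}"] = [(1000, 200, 500, 500)] * 4
        out = gene_dominance(_records_for_dominance(specs))
        res = dominance_summary(
            out,
            cis_only_genes=[f"cis{i}" for i in range(12)],
            trans_only_genes=[f"trans{i}" for i in range(12)],
        )
        assert res["cis_dominant_rate"] == 0.0
        assert res["trans_dominant_rate"] == 1.0
        assert res["fet_p"] < 0.05
        assert res["trans_maize_dominant"] == 12
        assert res["binom_p"] < 0.001

    def test_summary_symmetric_counts_p_one(self):
        specs = {}
        for i in range(4):
            specs[f"c{i}"] = [(1000, 200, 500, 500)] * 4  # dominant
            specs[f"t{i}"] = [(1000, 200, 500, 500)] * 4
            specs[f"c_add{i}"] = [(1000, 200, 500, 100)] * 4
            specs[f"t_add{i}"] = [(1000, 200, 500, 100)] * 4
        out = gene_dominance(_records_for_dominance(specs))
        res = dominance_summary(
            out,
            cis_only_genes=[f"c{i}" for i in range(4)] + [f"c_add{i}" for i in range(4)],
            trans_only_genes=[f"t{i}" for i in range(4)] + [f"t_add{i}" for i in range(4)],
        )
        assert res["fet_p"] == 1.0
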