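"""Ratio engine: pooling, library correction, per-cross and overall ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cistrans.ratios import (
    correct_parent_libsize,
    cross_ratios,
    overall_ratios,
    pool_replicates,
)
from conftest import make_counts


class TestPoolReplicates:
    def test_sums_over_replicates(self):
        counts = make_counts(
            [
                ("g1", "ear", "B73xTIL01", 1, 10, 5),
                ("g1", "ear", "B73xTIL01", 2, 20, 15),
            ]
        )
        pooled = pool_replicates(counts)
        assert len(pooled) == 1
        assert pooled.loc[0, "maize_count"] == 30
        assert pooled.loc[0, "teosinte_count"] == 20

    def test_single_replicate_identity(self):
        counts = make_counts([("g1", "ear", "B73", 1, 7, 0)])
        pooled = pool_replicates(counts)
        assert pooled.loc[0, "maize_count"] == 7

    def test_gene_absent_in_one_replicate_acts_as_zero(self):
        counts = make_counts(
            [
                ("g1", "ear", "B73xTIL01", 1, 10, 5),
                ("g2", "ear", "B73xTIL01", 2, 4, 4),
            ]
        )
        pooled = pool_replicates(counts).set_index("gene_id")
        assert pooled.loc["g1", "maize_count"] == 10
        assert pooled.loc["g2", "maize_count"] == 4


class TestCorrectParentLibsize:
    def test_larger_library_scaled_down(self):
        m, t = correct_parent_libsize(300, 100, 2e6, 1e6)
        assert (m, t) == (150, 100)

    def test_equal_libraries_unchanged(self):
        m, t = correct_parent_libsize(300, 100, 1e6, 1e6)
        assert (m, t) == (300, 100)

    def test_bankers_rounding(self):
        m, t = correct_parent_libsize(7, 10, 3e6, 1e6)
        assert (m, t) == (2, 10)  # 7/3 = 2.33 rounds to 2

    def test_zero_library_raises(self):
        with pytest.raises(ValueError):
            correct_parent_libsize(1, 1, 0, 1e6)

    @given(
        m=st.integers(0, 10**6),
        t=st.integers(0, 10**6),
        lm=st.floats(1e3, 1e8),
        lt=st.floats(1e3, 1e8),
        scale=st.floats(0.1, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, m, t, lm, lt, scale):
        # multiplying both library sizes by a constant changes nothing
        assert correct_parent_libsize(m, t, lm, lt) == correct_parent_libsize(
            m, t, lm * scale, lt * scale
        )


def _one_cross_counts(hyb=(150, 150), pm=200, pt=200, extra_gene=None):
    rows = [
        ("g1", "ear", "B73xTIL01", 1, hyb[0], hyb[1]),
        ("g1", "ear", "B73", 1, pm, 0),
        ("g1", "ear", "TIL01", 1, 0, pt),
    ]
    if extra_gene:
        rows += extra_gene
    return make_counts(rows)


def _one_cross_design():
    from cistrans.simulate import CrossDesign

    return CrossDesign(
        maize_lines=("B73",),
        teosinte_lines=("TIL01",),
        crosses=(("B73", "TIL01"),),
        replicates={"B73": 1, "TIL01": 1, "B73xTIL01": 1},
        tissues=("ear",),
    )


class TestCrossRatios:
    def test_balanced_counts_give_zero_log_ratio(self):
        rec = cross_ratios(pool_replicates(_one_cross_counts()), _one_cross_design())
        assert rec.loc[0, "log2_hybrid"] == 0.0

    def test_cis_and_trans_arithmetic(self):
        counts = _one_cross_counts(hyb=(200, 100), pm=100, pt=100)
        rec = cross_ratios(pool_replicates(counts), _one_cross_design())
        assert rec.loc[0, "log2_hybrid"] == pytest.approx(1.0)
        assert rec.loc[0, "log2_parent"] == pytest.approx(0.0)
        assert rec.loc[0, "trans_effect"] == pytest.approx(-1.0)

    def test_depth_filter_boundary(self):
        counts = _one_cross_counts(hyb=(50, 49), pm=100, pt=100)
        rec = cross_ratios(pool_replicates(counts), _one_cross_design(), min_depth=100)
        assert rec.loc[0, "depth_hybrid"] == 99
        assert not rec.loc[0, "passes_depth"]
        counts2 = _one_cross_counts(hyb=(50, 50), pm=100, pt=100)
        rec2 = cross_ratios(pool_replicates(counts2), _one_cross_design())
        assert rec2.loc[0, "passes_depth"].item()

    def test_zero_count_leaves_log_ratio_undefined(self):
        counts = _one_cross_counts(hyb=(300, 0), pm=100, pt=100)
        rec = cross_ratios(pool_replicates(counts), _one_cross_design())
        assert np.isnan(rec.loc[0, "log2_hybrid"])
        assert rec.loc[0, "passes_depth"].item()  # counts still usable for tests

    def test_missing_parent_flags_incomplete(self):
        counts = make_counts(
            [
                ("g1", "ear", "B73xTIL01", 1, 150, 150),
                ("g1", "ear", "B73", 1, 200, 0),
            ]
        )
        rec = cross_ratios(pool_replicates(counts), _one_cross_design())
        assert not rec.loc[0, "complete"]
        assert not rec.loc[0, "passes_depth"]


class TestOverallRatios:
    def test_single_cross_equals_cross_record(self, small_design):
        rows = []
        for m, t in [("B73", "TIL01")]:
            rows += [
                ("g1", "ear", f"{m}x{t}", 1, 180, 120),
                ("g1", "ear", m, 1, 300, 0),
                ("g1", "ear", t, 1, 0, 150),
            ]
        counts = make_counts(rows)
        design = _one_cross_design()
        rec = cross_ratios(pool_replicates(counts), design)
        ov = overall_ratios(rec, design)
        assert ov.loc[0, "sum_hybrid_m"] == rec.loc[0, "hybrid_m"]
        assert ov.loc[0, "wsum_parent_m"] == rec.loc[0, "parent_m"]
        assert ov.loc[0, "wsum_parent_t"] == rec.loc[0, "parent_t"]
        assert ov.loc[0, "log2_parent_overall"] == pytest.approx(
            rec.loc[0, "log2_parent"]
        )

    def test_shared_parent_not_double_counted(self):
        # two crosses share maize parent M1; teosinte parents have equal
        # counts and libraries: the overall parent ratio must equal the
        # single shared-parent ratio 200:100 = 2
        from cistrans.simulate import CrossDesign

        design = CrossDesign(
            maize_lines=("M1",),
            teosinte_lines=("T1", "T2"),
            crosses=(("M1", "T1"), ("M1", "T2")),
            replicates={g: 1 for g in ("M1", "T1", "T2", "M1xT1", "M1xT2")},
            tissues=("ear",),
        )
        # g0 pads every parent library to exactly 10,000 reads so the
        # library-size correction is the identity for this table
        counts = make_counts(
            [
                ("g1", "ear", "M1xT1", 1, 200, 100),
                ("g1", "ear", "M1xT2", 1, 200, 100),
                ("g1", "ear", "M1", 1, 200, 0),
                ("g1", "ear", "T1", 1, 0, 100),
                ("g1", "ear", "T2", 1, 0, 100),
                ("g0", "ear", "M1xT1", 1, 100, 100),
                ("g0", "ear", "M1xT2", 1, 100, 100),
                ("g0", "ear", "M1", 1, 9800, 0),
                ("g0", "ear", "T1", 1, 0, 9900),
                ("g0", "ear", "T2", 1, 0, 9900),
            ]
        )
        rec = cross_ratios(pool_replicates(counts), design)
        ov = overall_ratios(rec, design).set_index("gene_id")
        ratio = ov.loc["g1", "wsum_parent_m"] / ov.loc["g1", "wsum_parent_t"]
        assert ratio == pytest.approx(2.0)
        # hybrid side is a plain sum of passing records
        assert ov.loc["g1", "sum_hybrid_m"] == 400
        assert ov.loc["g1", "sum_hybrid_t"] == 200

    def test_all_crosses_failing_depth_removes_gene(self):
        counts = _one_cross_counts(hyb=(10, 10), pm=200, pt=200)
        design = _one_cross_design()
        rec = cross_ratios(pool_replicates(counts), design)
        ov = overall_ratios(rec, design)
        assert "g1" not in set(ov["gene_id"])

    def test_hybrid_sums_match_passing_records(self, default_design):
        from cistrans.simulate import SimParams, simulate_dataset

        counts, _ = simulate_dataset(default_design, SimParams(n_genes=60, seed=3))
        rec = cross_ratios(pool_replicates(counts), default_design)
        ov = overall_ratios(rec, default_design)
        ok = rec[rec["passes_depth"] & rec["complete"]]
        manual = ok.groupby(["gene_id", "tissue"])["hybrid_m"].sum()
        merged = ov.set_index(["gene_id", "tissue"])["sum_hybrid_m"]
        pd.testing.assert_series_equal(
            merged.sort_index(), manual.sort_index(), check_names=False
        )
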