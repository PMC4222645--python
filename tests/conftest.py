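"""Shared fixtures: small synthetic designs and count tables."""

import pandas as pd
import pytest

from cistrans.simulate import CrossDesign, SimParams, simulate_dataset, simulate_design


@pytest.fixture(scope="session")
def small_design():
    """Two maize x two teosinte lines, all four crosses, one tissue."""
    maize = ("B73", "MZ02")
    teosinte = ("TIL01", "TIL02")
    crosses = tuple((m, t) for m in maize for t in teosinte)
    reps = {g: 1 for g in maize + teosinte}
    reps.update({f"{m}x{t}": 1 for m, t in crosses})
    return CrossDesign(
        maize_lines=maize,
        teosinte_lines=teosinte,
        crosses=crosses,
        replicates=reps,
        tissues=("ear",),
    )


@pytest.fixture(scope="session")
def default_design():
    """The canonical 6 x 9 / 29-cross single-tissue design."""
    return simulate_design(tissues=("ear",), seed=11)


@pytest.fixture(scope="session")
def recovery_dataset(default_design):
    """Planted effects >= 1 log2, no allelic series: classifier food.

    2,000 genes at a per-gene pooled depth of several thousand reads, the
    regime where all three tests have essentially full power.
    """
    params = SimParams(
        n_genes=2000,
        seed=11,
        min_effect=1.0,
        sigma_cis_maize=0.0,
        sigma_cis_teosinte=0.0,
    )
    counts, truth = simulate_dataset(default_design, params)
    return counts, truth, params


def make_counts(rows):
    """Build a replicate-level count table from short tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "tissue",
            "genotype",
            "replicate",
            "maize_count",
            "teosinte_count",
        ],
    )
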