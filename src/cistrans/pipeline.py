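"""End-to-end orchestration: simulate -> ratios -> classify -> summaries.

Every stage writes deterministic TSVs (sorted rows, fixed float format)
into the run directory, plus a manifest recording versions, seeds and the
configuration hash so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .candidates import (
    build_lists,
    consistency_records,
    directional_bias_test,
    reference_bias_check,
    venn_counts,
)
from .classify import classify_all
from .config import RunConfig
from .divergence import cis_share_by_bin, loo_influence, loo_summary
from .dominance import dominance_summary, gene_dominance
from .io import read_counts, write_tsv
from .ratios import cross_ratios, overall_ratios, pool_replicates
from .simulate import CrossDesign, SimParams, simulate_dataset, simulate_design
from .variance import count_significant_parents, partition_all, r2_ratio_summary

logger = logging.getLogger(__name__)


def simulate_stage(out_dir, params: SimParams, design: CrossDesign | None = None):
    """Generate design, truth and counts; write them under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if design is None:
        design = simulate_design(seed=params.seed)
    counts, truth = simulate_dataset(design, params)
    with open(out / "design.yaml", "w") as fh:
        yaml.safe_dump(design.to_dict(), fh, sort_keys=True)
    write_tsv(counts, out / "counts.tsv")
    write_tsv(
        truth.effects.sort_values(["tissue", "gene_id"], kind="mergesort"),
        out / "truth_effects.tsv",
    )
    write_tsv(
        truth.line_devs.sort_values(["tissue", "gene_id", "line"], kind="mergesort"),
        out / "truth_line_devs.tsv",
    )
    return design, counts, truth


def load_design(path) -> CrossDesign:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"design file not found: {p}")
    with open(p) as fh:
        return CrossDesign.from_dict(yaml.safe_load(fh))


def run_all(config: RunConfig, out_dir, counts=None, design=None) -> Path:
    """Run every stage in dependency order; returns the run directory.

    Without ``counts``/``design`` a synthetic dataset is generated first
    from ``config.seed`` and ``config.n_genes``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if counts is None or design is None:
        params = SimParams(n_genes=config.n_genes, seed=config.seed)
        design, counts, _ = simulate_stage(out / "sim", params, design)
    elif isinstance(counts, (str, Path)):
        counts = read_counts(counts)

    pooled = pool_replicates(counts)
    write_tsv(pooled, out / "pooled_counts.tsv")

    records = cross_ratios(pooled, design, min_depth=config.min_depth)
    write_tsv(records, out / "cross_ratios.tsv")
    overall = overall_ratios(records, design)
    write_tsv(overall, out / "overall_ratios.tsv")

    calls, cat_summary = classify_all(overall, fdr=config.fdr_threshold)
    write_tsv(calls, out / "regulatory_calls.tsv")
    write_tsv(cat_summary, out / "category_summary.tsv")

    cons = consistency_records(
        records,
        min_crosses=config.min_crosses,
        min_maize=config.min_maize,
        min_teosinte=config.min_teosinte,
    )
    membership, union = build_lists(calls, cons)
    write_tsv(membership, out / "list_membership.tsv")
    write_tsv(union, out / "list_union.tsv")
    write_tsv(venn_counts(membership, design.tissues), out / "venn_counts.tsv")

    summaries: dict = {}
    cct_abc = membership[membership["list_class"] == "CCT"]
    for tissue in design.tissues:
        sub = cct_abc[cct_abc["tissue"] == tissue]
        if len(sub):
            summaries[f"directional_bias_{tissue}"] = directional_bias_test(sub)
    if len(cct_abc) and config.reference_line in design.maize_lines:
        try:
            summaries["reference_bias"] = reference_bias_check(
                records, cct_abc["gene_id"].unique(), config.reference_line
            )
        except ValueError as exc:
            logger.warning("reference bias check skipped: %s", exc)

    bins = cis_share_by_bin(overall, n_boot=config.bootstrap_reps, seed=config.seed)
    write_tsv(bins, out / "cis_share_bins.tsv")
    deltas = loo_influence(records)
    write_tsv(loo_summary(deltas), out / "loo_influence.tsv")

    partitions = partition_all(records, design)
    write_tsv(partitions, out / "variance_partition.tsv")
    write_tsv(count_significant_parents(partitions), out / "significant_parents.tsv")
    if len(partitions) >= 2:
        summaries["r2_ratio_all"] = r2_ratio_summary(partitions)

    dom = gene_dominance(records, alpha=config.dixon_alpha)
    write_tsv(dom, out / "dominance.tsv")
    cis_genes = union[
        (union["list_class"] == "cis_only") & (union["tier_level"] == "ABC")
    ]["gene_id"]
    trans_genes = union[
        (union["list_class"] == "trans_only") & (union["tier_level"] == "ABC")
    ]["gene_id"]
    try:
        summaries["dominance"] = dominance_summary(dom, cis_genes, trans_genes)
    except ValueError as exc:
        logger.warning("dominance summary skipped: %s", exc)

    config.to_yaml(out / "config.yaml")
    manifest = {
        "cistrans_version": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config_digest": config.digest(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "summaries.json", "w") as fh:
        json.dump(summaries, fh, indent=2, sort_keys=True, default=float)
    return out
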