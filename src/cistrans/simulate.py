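"""Synthetic allele-specific count data for a maize x teosinte F1 design.

The generator plants a known regulatory truth for every gene x tissue and
draws replicate-level allele counts from it, emulating the statistical
structure an F1-hybrid ASE analysis assumes:

* the F1 hybrid carries both alleles in a common trans environment, so the
  maize-allele count is binomial given the gene's allele-informative depth,
  with log-odds equal to the cross-specific cis effect;
* parent inbreds express only their own allele; the parent log2 ratio is
  cis + trans by construction;
* per-gene depth is negative-binomial (mean ``mean_depth``, dispersion
  ``alpha`` with variance mu + alpha*mu^2; alpha=0 degenerates to Poisson);
* library sizes vary log-normally between sequencing libraries;
* each inbred line carries its own small cis deviation (an allelic series),
  with less spread on the maize side than the teosinte side, mimicking the
  diversity loss of the domestication bottleneck.

"Ambiguous" is never planted; it can only arise from test outcomes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

HYBRID_SEP = "x"

#: Plantable regulatory categories (ambiguous arises only from testing).
TRUTH_CATEGORIES = (
    "conserved",
    "cis",
    "trans",
    "cis_plus_trans",
    "cis_x_trans",
    "compensatory",
)

DEFAULT_CATEGORY_MIX = {
    "conserved": 0.30,
    "cis": 0.15,
    "trans": 0.20,
    "cis_plus_trans": 0.10,
    "cis_x_trans": 0.10,
    "compensatory": 0.15,
}


def hybrid_name(maize_line: str, teosinte_line: str) -> str:
    return f"{maize_line}{HYBRID_SEP}{teosinte_line}"


def split_hybrid(genotype: str) -> tuple[str, str]:
    m, t = genotype.split(HYBRID_SEP, 1)
    return m, t


@dataclass(frozen=True)
class CrossDesign:
    """An F1 diallel-fragment design: which inbreds form which hybrids."""

    maize_lines: tuple[str, ...]
    teosinte_lines: tuple[str, ...]
    crosses: tuple[tuple[str, str], ...]
    replicates: dict[str, int]
    tissues: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.crosses)) != len(self.crosses):
            raise ValueError("crosses must be unique (maize, teosinte) pairs")
        for m, t in self.crosses:
            if m not in self.maize_lines or t not in self.teosinte_lines:
                raise ValueError(f"cross ({m}, {t}) references undeclared lines")
        for g, r in self.replicates.items():
            if r < 1:
                raise ValueError(f"replicate count for {g} must be >= 1")

    @property
    def genotypes(self) -> tuple[str, ...]:
        """All genotype labels: inbred lines then hybrids."""
        return (
            self.maize_lines
            + self.teosinte_lines
            + tuple(hybrid_name(m, t) for m, t in self.crosses)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "genotype": g,
                "kind": (
                    "maize"
                    if g in self.maize_lines
                    else "teosinte" if g in self.teosinte_lines else "hybrid"
                ),
                "replicates": self.replicates[g],
            }
            for g in self.genotypes
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "maize_lines": list(self.maize_lines),
            "teosinte_lines": list(self.teosinte_lines),
            "crosses": [list(c) for c in self.crosses],
            "replicates": dict(self.replicates),
            "tissues": list(self.tissues),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CrossDesign":
        return cls(
            maize_lines=tuple(d["maize_lines"]),
            teosinte_lines=tuple(d["teosinte_lines"]),
            crosses=tuple((m, t) for m, t in d["crosses"]),
            replicates={k: int(v) for k, v in d["replicates"].items()},
            tissues=tuple(d["tissues"]),
        )


@dataclass(frozen=True)
class SimParams:
    """Knobs of the generator.

    Effect scales are in log2 units.  Nonzero planted effect magnitudes are
    drawn as ``min_effect + |Normal(0, scale)|``; ``min_effect`` defaults to
    0 so small effects (which real data abounds in) occur.  ``mean_depth``
    is the expected allele-informative depth per gene per library, and
    ``dispersion`` the NB alpha (variance mu + alpha*mu^2).
    """

    n_genes: int = 2000
    category_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    cis_effect_scale: float = 1.0
    trans_effect_scale: float = 1.0
    min_effect: float = 0.0
    sigma_cis_maize: float = 0.23
    sigma_cis_teosinte: float = 0.25
    mean_depth: float = 150.0
    dispersion: float = 0.001
    libsize_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_mix sums to {total}, expected 1")
        unknown = set(self.category_mix) - set(TRUTH_CATEGORIES)
        # tolerate an explicit zero-weight "ambiguous" entry
        if unknown - {"ambiguous"} or self.category_mix.get("ambiguous", 0.0) > 0:
            raise ValueError(f"unknown or unplantable categories: {unknown}")
        for name in (
            "cis_effect_scale",
            "trans_effect_scale",
            "min_effect",
            "sigma_cis_maize",
            "sigma_cis_teosinte",
            "mean_depth",
            "dispersion",
            "libsize_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_(self, **kw) -> "SimParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class SimTruth:
    """Planted regulatory truth.

    ``effects``: gene_id, tissue, category, cis_effect, trans_effect.
    ``line_devs``: gene_id, tissue, line, dev — per-line cis deviations.
    For a cross (M, T) the effective cis effect is
    ``cis_effect + dev[M] - dev[T]`` and the parent log2 ratio is
    effective cis + trans.
    """

    effects: pd.DataFrame
    line_devs: pd.DataFrame


def simulate_design(
    n_maize: int = 6,
    n_teosinte: int = 9,
    n_crosses: int = 29,
    tissues: tuple[str, ...] = ("ear", "leaf", "stem"),
    replicate_mean: float = 1.96,
    seed: int = 0,
) -> CrossDesign:
    """Sample a cross design: ``n_crosses`` distinct pairs from the grid.

    Replicate counts per genotype are ``floor(replicate_mean)`` plus a
    Bernoulli draw of the fractional part, so their expectation equals
    ``replicate_mean`` (minimum 1).
    """
    if n_crosses > n_maize * n_teosinte:
        raise ValueError(
            f"n_crosses={n_crosses} exceeds the {n_maize}x{n_teosinte} grid"
        )
    if replicate_mean < 1:
        raise ValueError("replicate_mean must be >= 1")
    rng = np.random.default_rng(seed)
    maize = tuple(["B73"] + [f"MZ{i:02d}" for i in range(2, n_maize + 1)])
    teosinte = tuple(f"TIL{i:02d}" for i in range(1, n_teosinte + 1))
    grid = list(itertools.product(maize, teosinte))
    idx = rng.choice(len(grid), size=n_crosses, replace=False)
    crosses = tuple(grid[i] for i in sorted(idx))

    base = int(np.floor(replicate_mean))
    frac = replicate_mean - base
    genotypes = list(maize) + list(teosinte) + [hybrid_name(m, t) for m, t in crosses]
    reps = {g: base + int(rng.random() < frac) for g in genotypes}
    return CrossDesign(
        maize_lines=maize,
        teosinte_lines=teosinte,
        crosses=crosses,
        replicates=reps,
        tissues=tuple(tissues),
    )


def _draw_effects(rng, category, scale, min_effect, n):
    mag = min_effect + np.abs(rng.normal(0.0, scale, size=n))
    return mag


def simulate_truth(design: CrossDesign, params: SimParams) -> SimTruth:
    """Plant per-gene regulatory truth, independently per tissue.

    Category constraints: conserved c=t=0; cis-only t=0; trans-only c=0;
    cis+trans same sign; cis x trans opposite signs; compensatory t=-c.
    """
    rng = np.random.default_rng([int(params.seed), 101])
    labels = [c for c in TRUTH_CATEGORIES if params.category_mix.get(c, 0.0) > 0]
    probs = np.array([params.category_mix[c] for c in labels])
    probs = probs / probs.sum()
    gene_ids = np.array([f"g{i:06d}" for i in range(params.n_genes)])

    eff_frames = []
    dev_frames = []
    lines = list(design.maize_lines) + list(design.teosinte_lines)
    sigmas = np.array(
        [params.sigma_cis_maize] * len(design.maize_lines)
        + [params.sigma_cis_teosinte] * len(design.teosinte_lines)
    )
    for tissue in design.tissues:
        cat = rng.choice(len(labels), size=params.n_genes, p=probs)
        cat_names = np.array(labels, dtype=object)[cat]
        c_mag = _draw_effects(
            rng, cat_names, params.cis_effect_scale, params.min_effect, params.n_genes
        )
        t_mag = _draw_effects(
            rng, cat_names, params.trans_effect_scale, params.min_effect, params.n_genes
        )
        sign = rng.choice([-1.0, 1.0], size=params.n_genes)

        c = np.zeros(params.n_genes)
        t = np.zeros(params.n_genes)
        is_cis = cat_names == "cis"
        is_trans = cat_names == "trans"
        is_ct = cat_names == "cis_plus_trans"
        is_cxt = cat_names == "cis_x_trans"
        is_comp = cat_names == "compensatory"
        c[is_cis] = (sign * c_mag)[is_cis]
        t[is_trans] = (sign * t_mag)[is_trans]
        c[is_ct] = (sign * c_mag)[is_ct]
        t[is_ct] = (sign * t_mag)[is_ct]
        c[is_cxt] = (sign * c_mag)[is_cxt]
        t[is_cxt] = (-sign * t_mag)[is_cxt]
        c[is_comp] = (sign * c_mag)[is_comp]
        t[is_comp] = -c[is_comp]

        eff_frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "tissue": tissue,
                    "category": cat_names,
                    "cis_effect": c,
                    "trans_effect": t,
                }
            )
        )
        devs = rng.normal(0.0, 1.0, size=(params.n_genes, len(lines))) * sigmas
        dev_frames.append(
            pd.DataFrame(
                {
                    "gene_id": np.repeat(gene_ids, len(lines)),
                    "tissue": tissue,
                    "line": np.tile(lines, params.n_genes),
                    "dev": devs.ravel(),
                }
            )
        )
    return SimTruth(
        effects=pd.concat(eff_frames, ignore_index=True),
        line_devs=pd.concat(dev_frames, ignore_index=True),
    )


def _negbin(rng, mean, alpha):
    """NB(mean, alpha) via gamma-Poisson; alpha=0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
    return rng.poisson(lam)


def simulate_counts(
    design: CrossDesign, truth: SimTruth, params: SimParams
) -> pd.DataFrame:
    """Draw replicate-level allele counts for every genotype.

    Hybrids: total depth N ~ NB(mean_depth * lib, alpha); maize-allele count
    ~ Binomial(N, 2^c* / (1 + 2^c*)) with c* the cross-effective cis effect,
    so maize + teosinte counts equal N exactly.  Parents: a line's own-allele
    count is NB with mean proportional to lib * 2^{±(c+t)/2 + dev}, which
    makes the parent log2 ratio c* + t by construction.  Library factors are
    drawn log-normal (mean 1, CV ``libsize_cv``) per sequencing library.
    """
    rng = np.random.default_rng([int(params.seed), 202])
    n = params.n_genes
    gene_ids = np.array([f"g{i:06d}" for i in range(n)])
    cv = params.libsize_cv
    sig2 = np.log1p(cv * cv)
    lib_mu, lib_sigma = -sig2 / 2.0, np.sqrt(sig2)

    out = []
    for tissue in design.tissues:
        eff = truth.effects[truth.effects["tissue"] == tissue].set_index("gene_id")
        eff = eff.loc[gene_ids]
        c = eff["cis_effect"].to_numpy()
        t = eff["trans_effect"].to_numpy()
        devs = (
            truth.line_devs[truth.line_devs["tissue"] == tissue]
            .pivot(index="gene_id", columns="line", values="dev")
            .loc[gene_ids]
        )

        # parent inbreds: own-allele counts only
        for line in design.maize_lines + design.teosinte_lines:
            is_maize = line in design.maize_lines
            half = (c + t) / 2.0
            expo = (half if is_maize else -half) + devs[line].to_numpy()
            for rep in range(1, design.replicates[line] + 1):
                lib = rng.lognormal(lib_mu, lib_sigma)
                counts = _negbin(
                    rng, params.mean_depth * lib * np.exp2(expo), params.dispersion
                )
                out.append(
                    pd.DataFrame(
                        {
                            "gene_id": gene_ids,
                            "tissue": tissue,
                            "genotype": line,
                            "replicate": rep,
                            "maize_count": counts if is_maize else 0,
                            "teosinte_count": 0 if is_maize else counts,
                        }
                    )
                )

        # F1 hybrids: binomial allele split of an NB total depth
        for m_line, t_line in design.crosses:
            geno = hybrid_name(m_line, t_line)
            c_star = c + devs[m_line].to_numpy() - devs[t_line].to_numpy()
            p_maize = 1.0 / (1.0 + np.exp2(-c_star))
            for rep in range(1, design.replicates[geno] + 1):
                lib = rng.lognormal(lib_mu, lib_sigma)
                total = _negbin(rng, params.mean_depth * lib, params.dispersion)
                maize = rng.binomial(total, p_maize)
                out.append(
                    pd.DataFrame(
                        {
                            "gene_id": gene_ids,
                            "tissue": tissue,
                            "genotype": geno,
                            "replicate": rep,
                            "maize_count": maize,
                            "teosinte_count": total - maize,
                        }
                    )
                )
    counts = pd.concat(out, ignore_index=True)
    counts = counts.sort_values(
        ["tissue", "genotype", "replicate", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)
    return counts


def simulate_dataset(
    design: CrossDesign, params: SimParams
) -> tuple[pd.DataFrame, SimTruth]:
    """Convenience wrapper: truth then counts."""
    truth = simulate_truth(design, params)
    return simulate_counts(design, truth, params), truth
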