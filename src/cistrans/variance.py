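"""Partitioning F1 expression-ratio variance between maize and teosinte.

Cis regulatory diversity within each species shows up as variation of the
F1 hybrid log2 allele ratio across crosses.  A per-gene weighted linear
model regresses the per-cross hybrid log2 ratio on the maize-parent and
teosinte-parent factors (weights = hybrid depth); each side's R^2 is its
drop-one (Type II) weighted sum of squares over the total weighted sum of
squares, with a drop-one F-test per factor.  The ratio of mean maize R^2
to mean teosinte R^2 measures the relative cis diversity of the two
species — expected below 1 after the maize domestication bottleneck.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CrossDesign

logger = logging.getLogger(__name__)


def balance_design(records: pd.DataFrame, design: CrossDesign) -> pd.DataFrame:
    """Drop crosses whose teosinte parent occurs in exactly one cross.

    Singleton teosinte parents contribute a factor level with a single
    observation, confounding line effects with residual noise; removing
    their crosses balances the factor structure.
    """
    counts = pd.Series([t for _, t in design.crosses]).value_counts()
    singletons = set(counts[counts == 1].index)
    if not singletons:
        return records
    out = records[~records["teosinte_line"].isin(singletons)]
    if out.empty:
        logger.warning("balance_design removed every cross")
    return out


def _wls_sse(X: np.ndarray, y: np.ndarray, sw: np.ndarray) -> float:
    Xw = X * sw[:, None]
    yw = y * sw
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    return float(resid @ resid)


def _dummies(factor: np.ndarray) -> np.ndarray:
    levels = np.unique(factor)
    return (factor[:, None] == levels[None, 1:]).astype(float)


def fit_gene_model(
    log2_hybrid: np.ndarray,
    maize_factor: np.ndarray,
    teosinte_factor: np.ndarray,
    weights: np.ndarray,
) -> dict | None:
    """Weighted two-factor fit for one gene; returns None if unfittable.

    R^2 per side = (drop-one weighted SS increase) / (total weighted SS
    about the weighted mean); p per side from the drop-one F-test.  In an
    unbalanced design the two R^2 values need not sum to the model R^2.
    """
    y = np.asarray(log2_hybrid, dtype=float)
    w = np.asarray(weights, dtype=float)
    keep = np.isfinite(y) & np.isfinite(w) & (w > 0)
    y, w = y[keep], w[keep]
    mz = np.asarray(maize_factor)[keep]
    te = np.asarray(teosinte_factor)[keep]
    n = y.size
    if n == 0 or len(np.unique(mz)) < 2 or len(np.unique(te)) < 2:
        return None
    sw = np.sqrt(w)
    Dm, Dt = _dummies(mz), _dummies(te)
    ones = np.ones((n, 1))
    X_full = np.hstack([ones, Dm, Dt])
    rank = np.linalg.matrix_rank(X_full)
    df_resid = n - rank
    if df_resid < 1 or rank < X_full.shape[1]:
        return None  # rank deficient (confounded factors) or saturated
    ybar = np.average(y, weights=w)
    sst = float(w @ (y - ybar) ** 2)
    sse_full = _wls_sse(X_full, y, sw)
    out = {"n_crosses": int(n)}
    for name, drop, dfd in (
        ("maize", Dm, Dm.shape[1]),
        ("teosinte", Dt, Dt.shape[1]),
    ):
        X_red = np.hstack([ones, Dt if name == "maize" else Dm])
        sse_red = _wls_sse(X_red, y, sw)
        ss_drop = max(sse_red - sse_full, 0.0)
        out[f"r2_{name}"] = ss_drop / sst if sst > 0 else 0.0
        if sse_full <= 0 or sst <= 0:
            # perfect fit or constant response: no testable variation
            out[f"p_{name}"] = 1.0 if sst <= 0 else 0.0
            if sst <= 0:
                out[f"r2_{name}"] = 0.0
        else:
            f = (ss_drop / dfd) / (sse_full / df_resid)
            out[f"p_{name}"] = float(stats.f.sf(f, dfd, df_resid))
    return out


def partition_all(records: pd.DataFrame, design: CrossDesign) -> pd.DataFrame:
    """Fit the per-gene model for every gene x tissue on balanced records."""
    ok = records[records["complete"] & records["passes_depth"]]
    ok = balance_design(ok, design)
    ok = ok[np.isfinite(ok["log2_hybrid"])]
    rows = []
    for (gid, tissue), sub in ok.groupby(["gene_id", "tissue"], sort=True):
        res = fit_gene_model(
            sub["log2_hybrid"].to_numpy(),
            sub["maize_line"].to_numpy(),
            sub["teosinte_line"].to_numpy(),
            sub["depth_hybrid"].to_numpy(),
        )
        if res is None:
            continue
        res.update({"gene_id": gid, "tissue": tissue})
        rows.append(res)
    cols = [
        "gene_id",
        "tissue",
        "r2_maize",
        "r2_teosinte",
        "p_maize",
        "p_teosinte",
        "n_crosses",
    ]
    return pd.DataFrame(rows, columns=cols)


def r2_ratio_summary(
    partitions: pd.DataFrame, genes=None, se_method: str = "delta"
) -> dict:
    """Ratio of mean maize R^2 to mean teosinte R^2 (ratio of means).

    SE by the delta method for a ratio of two (correlated) means, or by a
    seeded gene bootstrap (``se_method="bootstrap"``).
    """
    df = partitions
    if genes is not None:
        df = df[df["gene_id"].isin(set(genes))]
    if len(df) < 2:
        raise ValueError("need at least two genes")
    rm = df["r2_maize"].to_numpy()
    rt = df["r2_teosinte"].to_numpy()
    mm, mt = rm.mean(), rt.mean()
    if mt == 0:
        raise ValueError("mean teosinte R^2 is zero")
    ratio = mm / mt
    n = len(df)
    if se_method == "delta":
        vm = rm.var(ddof=1) / n
        vt = rt.var(ddof=1) / n
        cov = np.cov(rm, rt, ddof=1)[0, 1] / n
        var = (vm / mt**2) + (mm**2 * vt / mt**4) - 2 * mm * cov / mt**3
        se = float(np.sqrt(max(var, 0.0)))
    elif se_method == "bootstrap":
        rng = np.random.default_rng(0)
        idx = rng.integers(0, n, size=(1000, n))
        boots = rm[idx].mean(axis=1) / rt[idx].mean(axis=1)
        se = float(boots.std(ddof=1))
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    return {"ratio": float(ratio), "se": se, "n_genes": n}


def count_significant_parents(
    partitions: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-tissue counts of maize-only / teosinte-only / both / neither
    significant parent terms at the (unadjusted) drop-one F-test level."""
    rows = []
    for tissue, sub in partitions.groupby("tissue", sort=True):
        sm = sub["p_maize"] < alpha
        st = sub["p_teosinte"] < alpha
        rows.append(
            {
                "tissue": tissue,
                "maize_only": int((sm & ~st).sum()),
                "teosinte_only": int((~sm & st).sum()),
                "both": int((sm & st).sum()),
                "neither": int((~sm & ~st).sum()),
            }
        )
    return pd.DataFrame(rows)
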