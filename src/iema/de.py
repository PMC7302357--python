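"""Cluster-versus-normal negative-binomial differential expression.

Counts are normalized by median-of-ratios size factors, a per-gene NB
dispersion (``var = mu + alpha * mu**2``) is estimated by method of moments
pooled across the two groups, and a Wald test on the log2 fold change is
computed via the delta method.  Genes are classified with the thresholds
used downstream for evasion annotation: adjusted p < 0.05 with |log2 FC|
above 2 is differential; a significant change below that magnitude is
"minimal".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "estimate_size_factors",
    "estimate_dispersion",
    "nb_wald_test",
    "bh_adjust",
    "classify_gene",
    "de_table",
]

DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5
DE_ALPHA = 0.05
DE_LFC = 2.0

DE_CLASSES = ("up", "down", "minimal_up", "minimal_down", "ns")


def estimate_size_factors(counts) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    The reference profile is the per-gene geometric mean over samples,
    restricted to genes with no zero count; each sample's factor is the
    median ratio of its counts to the reference.
    """
    arr = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, dtype=float)
    if arr.ndim != 2:
        raise ValueError("counts must be a genes x samples matrix")
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has all-positive counts; cannot form a geometric-mean "
            "reference (consider a pseudo-reference fallback)"
        )
    ref = np.exp(np.log(arr[allpos]).mean(axis=1))
    factors = np.median(arr[allpos] / ref[:, None], axis=0)
    return factors


def estimate_dispersion(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Method-of-moments NB dispersion pooled over two groups of normalized counts.

    ``alpha = max(floor, (pooled var - pooled mean) / pooled mean**2)`` where
    the pooled variance is the within-group variance (each group centered on
    its own mean) and the pooled mean averages over all observations.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 samples per group to estimate dispersion")
    n = a.size + b.size
    mean = (a.sum() + b.sum()) / n
    if mean <= 0:
        return DISPERSION_FLOOR
    ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    var = ss / (n - 2)
    return max(DISPERSION_FLOOR, (var - mean) / mean**2)


def nb_wald_test(
    cluster_counts,
    normal_counts,
    size_factors_cluster=None,
    size_factors_normal=None,
):
    """Per-gene NB Wald test of cluster vs normal.

    Inputs are genes x samples count matrices for the two groups.  Size
    factors default to median-of-ratios over the pooled matrix.  Returns a
    DataFrame with base_mean, log2fc, se, p.
    """
    cc = cluster_counts.to_numpy(dtype=float) if isinstance(cluster_counts, pd.DataFrame) else np.asarray(cluster_counts, dtype=float)
    nc = normal_counts.to_numpy(dtype=float) if isinstance(normal_counts, pd.DataFrame) else np.asarray(normal_counts, dtype=float)
    if cc.shape[1] < 2 or nc.shape[1] < 2:
        raise ValueError("both groups need at least 2 samples")
    if cc.shape[0] != nc.shape[0]:
        raise ValueError("gene dimensions differ between groups")
    if size_factors_cluster is None or size_factors_normal is None:
        pooled = np.hstack([cc, nc])
        sf = estimate_size_factors(pooled)
        size_factors_cluster = sf[: cc.shape[1]]
        size_factors_normal = sf[cc.shape[1]:]
    # rescale factors to geometric mean 1 so the normalized scale (and the
    # pseudo-count below) is invariant to a common factor multiple
    sfc = np.asarray(size_factors_cluster, dtype=float)
    sfn = np.asarray(size_factors_normal, dtype=float)
    gm = np.exp(np.log(np.concatenate([sfc, sfn])).mean())
    sfc, sfn = sfc / gm, sfn / gm
    xc = cc / sfc[None, :]
    xn = nc / sfn[None, :]

    n1, n0 = xc.shape[1], xn.shape[1]
    m1 = xc.mean(axis=1)
    m0 = xn.mean(axis=1)
    log2fc = np.log2((m1 + PSEUDOCOUNT) / (m0 + PSEUDOCOUNT))

    G = cc.shape[0]
    alpha = np.empty(G)
    for g in range(G):
        alpha[g] = estimate_dispersion(xc[g], xn[g])

    # delta method on log2 of the pseudo-counted group means
    var_m1 = (m1 + alpha * m1**2) / n1
    var_m0 = (m0 + alpha * m0**2) / n0
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt((var_m1 / (m1 + PSEUDOCOUNT) ** 2 + var_m0 / (m0 + PSEUDOCOUNT) ** 2) / ln2sq)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)

    base_mean = np.hstack([xc, xn]).mean(axis=1)
    idx = cluster_counts.index if isinstance(cluster_counts, pd.DataFrame) else pd.RangeIndex(G)
    return pd.DataFrame(
        {"base_mean": base_mean, "log2fc": log2fc, "se": se, "p": p}, index=idx
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_gene(log2fc: float, padj: float, alpha: float = DE_ALPHA, lfc: float = DE_LFC) -> str:
    """DE class for one gene: up / down / minimal_up / minimal_down / ns."""
    if not 0.0 <= padj <= 1.0:
        raise ValueError("padj must lie in [0, 1]")
    if padj < alpha:
        if log2fc > lfc:
            return "up"
        if log2fc < -lfc:
            return "down"
        if 0.0 < log2fc <= lfc:
            return "minimal_up"
        if -lfc <= log2fc < 0.0:
            return "minimal_down"
    return "ns"


def de_table(cluster_counts, normal_counts, **kwargs) -> pd.DataFrame:
    """Full DE table: Wald test + BH adjustment + classification."""
    tab = nb_wald_test(cluster_counts, normal_counts, **kwargs)
    tab["padj"] = bh_adjust(tab["p"].to_numpy())
    tab["de_class"] = [
        classify_gene(l, q) for l, q in zip(tab["log2fc"], tab["padj"])
    ]
    return tab
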