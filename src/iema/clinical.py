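"""Exact association tests between cluster membership and clinical categories.

``fisher_exact_2xk`` generalizes Fisher's exact test to a 2 x k table by
full enumeration: all tables with the observed margins are enumerated, each
weighted by its multivariate hypergeometric probability, and the two-sided
p-value sums the probabilities of tables at most as probable as the
observed one (the probability-ordering convention of the classical test).

``associate_clusters`` compares each cluster's category counts against the
column totals over all clustered samples.  Comparing against the totals —
with the cluster included — rather than against the complement is what
reproduces the published contingency arithmetic this pipeline mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

__all__ = ["ContingencyResult", "fisher_exact_2xk", "associate_clusters", "table_probabilities"]

REL_TOL = 1e-7


@dataclass
class ContingencyResult:
    cluster: str
    variable: str
    categories: list
    cluster_counts: list
    rest_counts: list
    p: float
    significant: bool
    dropped_categories: list = field(default_factory=list)
    n_missing: int = 0

    def to_dict(self) -> dict:
        return {
            "cluster": self.cluster,
            "variable": self.variable,
            "categories": list(self.categories),
            "cluster_counts": [int(c) for c in self.cluster_counts],
            "rest_counts": [int(c) for c in self.rest_counts],
            "p": float(self.p),
            "significant": bool(self.significant),
            "dropped_categories": list(self.dropped_categories),
            "n_missing": int(self.n_missing),
        }


def _validate_counts(v) -> np.ndarray:
    arr = np.asarray(v)
    if arr.ndim != 1:
        raise ValueError("count vectors must be 1-D")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.any(arr != np.round(arr)):
            raise ValueError("counts must be integers")
        arr = arr.astype(np.int64)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr.astype(np.int64)


def table_probabilities(row1: np.ndarray, row2: np.ndarray):
    """Enumerate all 2xk tables with the given margins.

    Yields ``(top_row_tuple, probability)`` under the multivariate
    hypergeometric distribution induced by the margins.
    """
    col = row1 + row2
    n1 = int(row1.sum())
    N = int(col.sum())
    denom = comb(N, n1)
    k = len(col)

    def rec(j, left, prefix, weight):
        if j == k - 1:
            if 0 <= left <= col[j]:
                yield prefix + (left,), weight * comb(int(col[j]), left) / denom
            return
        remaining_capacity = int(col[j + 1:].sum())
        lo = max(0, left - remaining_capacity)
        hi = min(int(col[j]), left)
        for a in range(lo, hi + 1):
            yield from rec(j + 1, left - a, prefix + (a,), weight * comb(int(col[j]), a))

    yield from rec(0, n1, (), 1.0)


def fisher_exact_2xk(cluster_counts, rest_counts) -> float:
    """Two-sided exact p for a 2 x k contingency table by enumeration.

    The p-value sums the probabilities of all margin-preserving tables
    whose probability does not exceed the observed table's (within a
    relative tolerance guarding against float round-off).
    """
    r1 = _validate_counts(cluster_counts)
    r2 = _validate_counts(rest_counts)
    if len(r1) != len(r2):
        raise ValueError("count vectors must have equal length")
    if len(r1) < 2:
        raise ValueError("need at least 2 categories")
    keep = (r1 + r2) > 0
    r1, r2 = r1[keep], r2[keep]
    if len(r1) < 2:
        raise ValueError("fewer than 2 non-empty categories")
    if r1.sum() == 0 or r2.sum() == 0:
        raise ValueError("both rows must have positive totals")

    obs = tuple(int(x) for x in r1)
    p_obs = None
    tables = []
    for top, prob in table_probabilities(r1, r2):
        tables.append((top, prob))
        if top == obs:
            p_obs = prob
    assert p_obs is not None
    cutoff = p_obs * (1.0 + REL_TOL)
    p = sum(prob for _, prob in tables if prob <= cutoff)
    return min(1.0, float(p))


def associate_clusters(
    assignment, clinical: pd.DataFrame, variable: str, alpha: float = 0.05
) -> list:
    """Exact association of every cluster with one categorical variable.

    For each cluster, the cluster's category counts are tested against the
    column totals over all clustered samples (all-zero categories dropped).
    Samples with a missing value are excluded and counted per cluster.
    """
    if variable not in clinical.columns:
        raise ValueError(f"variable {variable!r} not in clinical table")
    labels = assignment.labels()
    clustered = [s for s, c in labels.items() if c != "unclustered"]
    if not clustered:
        raise ValueError("no clustered samples")

    values = clinical[variable]
    categories = sorted({v for v in values.loc[values.index.intersection(clustered)].dropna()})
    if len(categories) < 2:
        raise ValueError(f"variable {variable!r} has fewer than 2 observed categories")

    def count_vec(samples):
        vals = values.reindex(samples)
        n_missing = int(vals.isna().sum())
        counts = [int((vals == cat).sum()) for cat in categories]
        return counts, n_missing

    total_counts, _ = count_vec(clustered)
    results = []
    for cid, samples, _ in assignment.clusters:
        if set(samples) == set(clustered):
            raise ValueError("cluster contains all clustered samples; comparison row is empty")
        ccounts, n_missing = count_vec(samples)
        keep = [i for i, t in enumerate(total_counts) if t > 0]
        dropped = [categories[i] for i in range(len(categories)) if i not in keep]
        c1 = [ccounts[i] for i in keep]
        c2 = [total_counts[i] for i in keep]
        p = fisher_exact_2xk(c1, c2)
        results.append(
            ContingencyResult(
                cluster=cid,
                variable=variable,
                categories=[categories[i] for i in keep],
                cluster_counts=c1,
                rest_counts=c2,
                p=p,
                significant=p <= alpha,
                dropped_categories=dropped,
                n_missing=n_missing,
            )
        )
    return results
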