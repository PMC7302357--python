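"""Sequential plaid clustering into disjoint patient clusters.

One retained plaid layer is fitted per round on the remaining samples'
(re-centered) matrix; its sample members become the next cluster and are
removed.  The loop stops when no layer is retained or the retained layer
covers less than ``min_frac`` of the ORIGINAL cohort — percentages in a
sequential scheme only make sense against a fixed denominator.  Genes are
not removed between rounds, so a gene may define several clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plaid import PlaidParams, fit_layer, layer_significance

__all__ = ["ClusterAssignment", "sequential_cluster"]

UNCLUSTERED = "unclustered"


@dataclass
class ClusterAssignment:
    """Disjoint sample clusters plus the unclustered remainder."""

    clusters: list  # [(cluster_id, sample id list, gene id list), ...] in discovery order
    unclustered: list
    n_total: int
    min_frac: float

    def labels(self) -> dict:
        out = {s: cid for cid, samples, _ in self.clusters for s in samples}
        out.update({s: UNCLUSTERED for s in self.unclustered})
        return out

    @property
    def n_clustered(self) -> int:
        return sum(len(samples) for _, samples, _ in self.clusters)

    def summary(self) -> pd.DataFrame:
        """Cluster sizes with percentages under both denominators."""
        rows = []
        nc = self.n_clustered
        for cid, samples, genes in self.clusters:
            rows.append(
                {
                    "cluster": cid,
                    "n_samples": len(samples),
                    "n_genes": len(genes),
                    "pct_of_cohort": 100.0 * len(samples) / self.n_total,
                    "pct_of_clustered": (100.0 * len(samples) / nc) if nc else float("nan"),
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "clusters": [
                {"cluster": cid, "samples": list(samples), "genes": list(genes)}
                for cid, samples, genes in self.clusters
            ],
            "unclustered": list(self.unclustered),
            "n_total": self.n_total,
            "min_frac": self.min_frac,
        }


def sequential_cluster(
    matrix: pd.DataFrame, params: PlaidParams | None = None, min_frac: float = 0.05
) -> ClusterAssignment:
    """Disjoint clusters by repeated single-layer plaid fits.

    ``matrix`` is genes x samples on the plaid (log, normalized,
    gene-centered) scale; centering happens once, over the full cohort, so
    every round's layer is an excursion from the same cohort-wide baseline
    rather than from a shrinking remainder whose mean drifts with each
    removal.  Each round fits one layer on the remaining samples' columns,
    applies the permutation retention test, and records the layer's samples
    as the next cluster.  Stops when no layer is retained or a retained
    layer has fewer than ``ceil(min_frac * n_total)`` samples.
    """
    if not 0.0 < min_frac < 1.0:
        raise ValueError("min_frac must lie in (0, 1)")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    n_total = matrix.shape[1]
    min_size = math.ceil(min_frac * n_total)
    rng = np.random.default_rng(params.seed if params else 0)
    if params is None:
        params = PlaidParams()

    remaining = list(matrix.columns)
    clusters = []
    k = 0
    full = matrix.to_numpy(dtype=float)
    while len(remaining) >= max(2, min_size):
        sub = matrix[remaining].to_numpy(dtype=float)
        layer = fit_layer(sub, params)
        if layer.is_empty or not layer_significance(
            layer, sub, params, rng, null_matrix=full
        ):
            break
        members = [remaining[j] for j in np.flatnonzero(layer.sample_members)]
        if len(members) < min_size:
            break
        genes = [matrix.index[i] for i in np.flatnonzero(layer.gene_members)]
        k += 1
        clusters.append((f"cluster_{k}", members, genes))
        member_set = set(members)
        remaining = [s for s in remaining if s not in member_set]
    return ClusterAssignment(clusters, remaining, n_total, min_frac)
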