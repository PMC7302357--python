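"""Immune-cell fraction summaries from CIBERSORT-style tables.

The lymphocyte total follows the convention of summing B-cell, T-cell and
NK-cell subsets of the LM22 signature (plasma cells excluded — they are a
separate LM22 population; the column set is configurable).  Per-cell-type
cluster-vs-normal comparisons use Welch's two-sample t-test with the usual
significance stars, no multiplicity correction across cell types.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["LYMPHOCYTE_COLUMNS", "total_lymphocytes", "compare_cell_abundance", "cluster_cell_summary"]

LYMPHOCYTE_COLUMNS = (
    "B cells naive",
    "B cells memory",
    "T cells CD8",
    "T cells CD4 naive",
    "T cells CD4 memory resting",
    "T cells CD4 memory activated",
    "T cells follicular helper",
    "T cells regulatory (Tregs)",
    "T cells gamma delta",
    "NK cells resting",
    "NK cells activated",
)


def total_lymphocytes(row, columns: tuple = LYMPHOCYTE_COLUMNS) -> float:
    """Sum of the designated lymphocyte columns for one sample row."""
    missing = [c for c in columns if c not in row.index]
    if missing:
        raise ValueError(f"missing lymphocyte columns: {missing}")
    return float(row[list(columns)].sum())


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_cell_abundance(cluster_rows: pd.DataFrame, normal_rows: pd.DataFrame, cell_type: str):
    """Welch t-test on one cell type's fractions, cluster vs normal.

    Returns ``(t, p, stars)``.
    """
    for df in (cluster_rows, normal_rows):
        if cell_type not in df.columns:
            raise ValueError(f"cell type {cell_type!r} not in fraction table")
        if len(df) < 2:
            raise ValueError("both groups need at least 2 samples")
    x = cluster_rows[cell_type].to_numpy(dtype=float)
    y = normal_rows[cell_type].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(f"zero variance in a group for {cell_type!r}")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p), significance_stars(float(p))


def cluster_cell_summary(
    fractions: pd.DataFrame, labels: dict, normal_samples: list
) -> pd.DataFrame:
    """Per-cluster, per-cell-type summary (mean, sd, n, t, p, stars) vs normals.

    ``labels`` maps tumor sample id -> cluster id.  Cell types whose
    comparison is degenerate (zero variance) get NaN statistics.
    """
    normals = fractions.loc[[s for s in normal_samples if s in fractions.index]]
    rows = []
    clusters = sorted(set(labels.values()))
    for cid in clusters:
        members = [s for s, c in labels.items() if c == cid and s in fractions.index]
        sub = fractions.loc[members]
        for cell in fractions.columns:
            rec = {
                "cluster": cid,
                "cell_type": cell,
                "n": len(sub),
                "mean": float(sub[cell].mean()),
                "sd": float(sub[cell].std(ddof=1)),
            }
            try:
                t, p, stars = compare_cell_abundance(sub, normals, cell)
            except ValueError:
                t, p, stars = float("nan"), float("nan"), ""
            rec.update({"t": t, "p": p, "stars": stars})
            rows.append(rec)
    return pd.DataFrame(rows)
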