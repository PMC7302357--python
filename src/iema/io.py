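"""Readers and writers for the pipeline's tabular formats.

Counts are genes x samples TSV (first column gene symbol, header row of
sample ids), HTSeq-count style integers.  Sample roles (tumor vs adjacent
normal) come from a sidecar TSV (``sample<TAB>role``); without one, sample
ids beginning with ``N`` or ``normal`` are treated as normals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("iema")

__all__ = ["CountMatrix", "read_counts", "read_gene_list", "read_clinical", "read_fractions"]

ROLES = ("tumor", "normal")


@dataclass
class CountMatrix:
    """Non-negative integer gene-by-sample counts with sample role labels."""

    counts: pd.DataFrame
    roles: pd.Series

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            g, s = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count for gene {self.counts.index[g]!r} in sample "
                f"{self.counts.columns[s]!r}"
            )
        self.roles = self.roles.reindex(self.counts.columns)
        if self.roles.isna().any():
            missing = self.roles[self.roles.isna()].index.tolist()
            raise ValueError(f"samples without a role label: {missing}")
        bad = set(self.roles.unique()) - set(ROLES)
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")

    @property
    def genes(self) -> list:
        return list(self.counts.index)

    @property
    def samples(self) -> list:
        return list(self.counts.columns)

    def tumor(self) -> pd.DataFrame:
        return self.counts.loc[:, self.roles == "tumor"]

    def normal(self) -> pd.DataFrame:
        return self.counts.loc[:, self.roles == "normal"]

    def write_tsv(self, counts_path, roles_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene")
        if roles_path is not None:
            self.roles.rename("role").to_csv(roles_path, sep="\t", index_label="sample")


def _infer_roles(samples) -> pd.Series:
    role = [
        "normal" if str(s).lower().startswith(("n", "normal")) else "tumor"
        for s in samples
    ]
    return pd.Series(role, index=samples)


def read_counts(path, gene_list=None, roles_path=None) -> CountMatrix:
    """Read a counts TSV, collapse duplicate genes, restrict to a gene list."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"empty counts file: {path}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.isfinite(arr)) or np.any(arr != np.round(arr)):
            bad = np.argwhere((arr != np.round(arr)) | ~np.isfinite(arr))
            g, s = bad[0]
            raise ValueError(
                f"non-integer count for gene {df.index[g]!r} in sample {df.columns[s]!r}"
            )
        df = df.astype(np.int64)

    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        logger.warning("collapsing %d duplicate gene symbols by sum: %s",
                       len(dups), ", ".join(map(str, dups[:10])))
        df = df.groupby(level=0, sort=False).sum()

    if gene_list is not None:
        wanted = list(dict.fromkeys(gene_list))
        present = [g for g in wanted if g in df.index]
        missing = [g for g in wanted if g not in df.index]
        if not present:
            raise ValueError("no overlap between counts file and the immune gene list")
        if missing:
            logger.warning("%d gene-list symbols absent from the counts file: %s%s",
                           len(missing), ", ".join(missing[:10]),
                           "..." if len(missing) > 10 else "")
        df = df.loc[present]

    if roles_path is not None:
        roles = pd.read_csv(roles_path, sep="\t", index_col=0).iloc[:, 0]
    else:
        roles = _infer_roles(df.columns)
    return CountMatrix(df, roles)


def read_gene_list(path) -> list:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    if not out:
        raise ValueError(f"empty gene list: {path}")
    return out


def read_clinical(path) -> pd.DataFrame:
    """Clinical TSV: sample id index plus categorical columns; blanks -> NaN."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        raise ValueError("duplicate sample ids in clinical table")
    return df


def read_fractions(path, strict_columns: tuple | None = None) -> pd.DataFrame:
    """CIBERSORT-style fraction CSV; trailing statistic columns are dropped."""
    df = pd.read_csv(path, index_col=0)
    for stat_col in ("P-value", "Correlation", "RMSE", "Absolute score"):
        if stat_col in df.columns:
            df = df.drop(columns=stat_col)
    if strict_columns is not None:
        missing = [c for c in strict_columns if c not in df.columns]
        if missing:
            raise ValueError(f"fraction table missing cell-type columns: {missing}")
        df = df.loc[:, list(strict_columns)]
    return df.astype(float)
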