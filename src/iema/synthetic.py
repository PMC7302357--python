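"""Seeded synthetic cohort generator with planted ground truth.

Emulates the structure of a bulk tumor immune-transcriptomics cohort:
negative-binomial gene counts, disjoint patient clusters planted as
additive log2-scale plaid layers over cluster-specific gene subsets,
per-cluster immune-evasion expression patterns written into the
cancer-immunity panel genes, cluster-enriched categorical clinical
variables, and Dirichlet immune-cell fractions with cluster-specific
concentration shifts.  Every downstream stage of the pipeline can be
scored against the planted truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .iem import CancerImmunityPanel, load_default_panel
from .io import CountMatrix

__all__ = [
    "LM22_COLUMNS",
    "CohortConfig",
    "SyntheticCohort",
    "generate_counts",
    "generate_clinical",
    "generate_fractions",
    "generate_cohort",
]

LM22_COLUMNS = (
    "B cells naive",
    "B cells memory",
    "Plasma cells",
    "T cells CD8",
    "T cells CD4 naive",
    "T cells CD4 memory resting",
    "T cells CD4 memory activated",
    "T cells follicular helper",
    "T cells regulatory (Tregs)",
    "T cells gamma delta",
    "NK cells resting",
    "NK cells activated",
    "Monocytes",
    "Macrophages M0",
    "Macrophages M1",
    "Macrophages M2",
    "Dendritic cells resting",
    "Dendritic cells activated",
    "Mast cells resting",
    "Mast cells activated",
    "Eosinophils",
    "Neutrophils",
)

BACKGROUND = "background"

# Gleason-category and T-stage baseline frequencies for the unenriched
# population; chosen to resemble a typical prostatectomy cohort where
# Gleason 7 dominates and pathologic T2/T3 cover nearly all patients.
GLEASON_BASELINE = {"le6": 0.10, "eq7": 0.49, "ge8": 0.41}
TSTAGE_BASELINE = {"T1": 0.02, "T2": 0.37, "T3": 0.58, "T4": 0.03}

# Expression patterns planted for each evasion mechanism: genes that get
# +layer_effect in that cluster's samples.  Ignorance plants nothing (all
# cycle genes stay at the normal baseline); impaired antigen presentation
# activates trafficking/infiltration while presentation and killing stay
# silent.
_MECHANISM_STEPS_UP = {
    "impaired_antigen_presentation": ("trafficking", "infiltration"),
}

DEFAULT_IEM_TRUTH = {
    "cluster_1": frozenset({"ignorance"}),
    "cluster_2": frozenset({"ignorance", "tolerance:CTLA4"}),
    "cluster_3": frozenset({"ignorance", "counterattack:DcR3"}),
    "cluster_4": frozenset({"impaired_antigen_presentation", "tolerance:PD-1"}),
}


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_tumor: int = 300
    n_normal: int = 30
    n_genes: int = 400
    n_clusters: int = 4
    cluster_fracs: tuple = (0.30, 0.25, 0.20, 0.15)
    base_log_mean_range: tuple = (3.0, 8.0)
    layer_effect: float = 4.0
    nb_dispersion: float = 0.05
    genes_per_cluster: int = 40
    iem_truth: dict = field(default_factory=lambda: dict(DEFAULT_IEM_TRUTH))
    clinical_enrichment: dict = field(
        default_factory=lambda: {"cluster_2": {"gleason_cat": {"ge8": 8.0}}}
    )
    fraction_shifts: dict = field(
        default_factory=lambda: {"cluster_4": {"T cells regulatory (Tregs)": 5.0}}
    )
    allow_small_clusters: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tumor, self.n_normal, self.n_genes, self.n_clusters) < 1:
            raise ValueError("all counts must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        fr = tuple(self.cluster_fracs)
        if len(fr) != self.n_clusters:
            raise ValueError("cluster_fracs must have one entry per cluster")
        if any(f < 0 for f in fr):
            raise ValueError("cluster_fracs must be non-negative")
        if not self.allow_small_clusters and any(0 < f < 0.05 for f in fr):
            raise ValueError(
                "cluster_fracs below 0.05 would be dropped by the sequential stop "
                "rule; set allow_small_clusters=True if that is intended"
            )
        if sum(fr) > 1.0 + 1e-12:
            raise ValueError("cluster_fracs sum must be <= 1")

    def cluster_labels(self) -> list[str]:
        return [f"cluster_{k + 1}" for k in range(self.n_clusters)]


@dataclass
class SyntheticCohort:
    counts: CountMatrix
    true_clusters: dict
    true_iem: dict
    clinical: pd.DataFrame
    fractions: pd.DataFrame
    panel: CancerImmunityPanel
    config: CohortConfig

    def write(self, outdir) -> None:
        """Write counts TSV, clinical TSV, fractions CSV and truth JSON."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.counts.write_tsv(out / "counts.tsv", out / "sample_roles.tsv")
        self.clinical.to_csv(out / "clinical.tsv", sep="\t", index_label="sample")
        self.fractions.to_csv(out / "fractions.csv", index_label="Mixture")
        truth = {
            "true_clusters": self.true_clusters,
            "true_iem": {c: sorted(m) for c, m in self.true_iem.items()},
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))


def _assign_clusters(config: CohortConfig) -> dict:
    """Deterministic sample -> cluster map; leading samples fill clusters in order."""
    labels = {}
    sizes = [int(round(f * config.n_tumor)) for f in config.cluster_fracs]
    names = config.cluster_labels()
    pos = 0
    for name, size in zip(names, sizes):
        for i in range(pos, min(pos + size, config.n_tumor)):
            labels[f"T{i + 1:04d}"] = name
        pos += size
    for i in range(pos, config.n_tumor):
        labels[f"T{i + 1:04d}"] = BACKGROUND
    return labels


def _gene_universe(config: CohortConfig, panel: CancerImmunityPanel) -> list[str]:
    panel_genes = sorted(panel.all_genes())
    if config.n_genes < len(panel_genes) + config.n_clusters * config.genes_per_cluster:
        raise ValueError(
            "n_genes too small for the panel plus the planted cluster signatures"
        )
    n_filler = config.n_genes - len(panel_genes)
    filler = [f"GENE{i + 1:05d}" for i in range(n_filler)]
    return panel_genes + filler


def generate_counts(
    config: CohortConfig, panel: CancerImmunityPanel | None = None
) -> tuple[CountMatrix, dict]:
    """NB count matrix with planted plaid layers and evasion patterns.

    Per gene g and sample s the count is NB with mean
    ``2**(b_g + sum of planted layer effects at (g, s))`` and dispersion
    ``nb_dispersion`` (gamma-Poisson mixture, var = mu + alpha mu**2).
    Each cluster's signature genes carry +/- ``layer_effect``; evasion
    patterns add ``+layer_effect`` to the corresponding panel genes.
    Normal samples carry baseline only.
    """
    if panel is None:
        panel = load_default_panel()
    rng = np.random.default_rng(config.seed)
    genes = _gene_universe(config, panel)
    true_clusters = _assign_clusters(config)
    tumor_ids = list(true_clusters)
    normal_ids = [f"N{i + 1:04d}" for i in range(config.n_normal)]
    samples = tumor_ids + normal_ids

    gidx = {g: i for i, g in enumerate(genes)}
    G, S = len(genes), len(samples)
    lo, hi = config.base_log_mean_range
    base = rng.uniform(lo, hi, size=G)
    logmean = np.tile(base[:, None], (1, S))

    panel_genes = panel.all_genes()
    filler_pool = [g for g in genes if g not in panel_genes]
    rng.shuffle(filler_pool)

    names = config.cluster_labels()
    for k, name in enumerate(names):
        cols = [j for j, s in enumerate(tumor_ids) if true_clusters[s] == name]
        if not cols:
            continue
        sig = filler_pool[k * config.genes_per_cluster : (k + 1) * config.genes_per_cluster]
        half = len(sig) // 2
        for g in sig[:half]:
            logmean[gidx[g], cols] += config.layer_effect
        for g in sig[half:]:
            logmean[gidx[g], cols] -= config.layer_effect
        for mech in config.iem_truth.get(name, ()):  # evasion expression patterns
            for step in _MECHANISM_STEPS_UP.get(mech, ()):
                for g in panel.steps[step]:
                    logmean[gidx[g], cols] += config.layer_effect
            for g in panel.checkpoint_genes.get(mech, ()):
                logmean[gidx[g], cols] += config.layer_effect
            for g in panel.decoy_genes.get(mech, ()):
                logmean[gidx[g], cols] += config.layer_effect

    mu = 2.0**logmean
    alpha = config.nb_dispersion
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    counts = rng.poisson(lam).astype(np.int64)

    roles = pd.Series(
        ["tumor"] * len(tumor_ids) + ["normal"] * len(normal_ids), index=samples
    )
    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), roles)
    return cm, true_clusters


def generate_clinical(
    true_clusters: dict, enrichment: dict, seed: int
) -> pd.DataFrame:
    """Categorical clinical table with cluster-enriched category odds.

    Each sample's category is drawn from the baseline simplex reweighted by
    its cluster's multipliers and renormalized.
    """
    variables = {"gleason_cat": GLEASON_BASELINE, "t_stage": TSTAGE_BASELINE}
    known = set(true_clusters.values()) | {BACKGROUND}
    for cluster, per_var in enrichment.items():
        if cluster not in known:
            raise ValueError(f"unknown cluster label in enrichment: {cluster!r}")
        for var, mults in per_var.items():
            if var not in variables:
                raise ValueError(f"unknown clinical variable: {var!r}")
            for cat, m in mults.items():
                if cat not in variables[var]:
                    raise ValueError(f"unknown category {cat!r} for {var!r}")
                if m <= 0:
                    raise ValueError("enrichment multipliers must be positive")

    rng = np.random.default_rng(seed)
    rows = {}
    for sample, cluster in true_clusters.items():
        row = {}
        for var, baseline in variables.items():
            cats = list(baseline)
            w = np.array([baseline[c] for c in cats], dtype=float)
            mults = enrichment.get(cluster, {}).get(var, {})
            for c, m in mults.items():
                w[cats.index(c)] *= m
            w /= w.sum()
            row[var] = cats[rng.choice(len(cats), p=w)]
        rows[sample] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def generate_fractions(
    true_clusters: dict,
    shift_config: dict,
    seed: int,
    base_concentration: float = 2.0,
    normal_ids: list | None = None,
) -> pd.DataFrame:
    """Dirichlet immune-cell fraction table in the LM22 column layout.

    Rows are drawn from ``Dirichlet(base_concentration * cluster multipliers)``
    over the 22 cell types; rows sum to one by construction.
    """
    if base_concentration <= 0:
        raise ValueError("base_concentration must be positive")
    for cluster, mults in shift_config.items():
        for col, m in mults.items():
            if col not in LM22_COLUMNS:
                raise ValueError(f"unknown LM22 column: {col!r}")
            if m <= 0:
                raise ValueError("concentration multipliers must be positive")

    rng = np.random.default_rng(seed)
    samples = list(true_clusters) + list(normal_ids or [])
    rows = np.empty((len(samples), len(LM22_COLUMNS)))
    for i, sample in enumerate(samples):
        conc = np.full(len(LM22_COLUMNS), float(base_concentration))
        cluster = true_clusters.get(sample)
        for col, m in shift_config.get(cluster, {}).items():
            conc[LM22_COLUMNS.index(col)] *= m
        rows[i] = rng.dirichlet(conc)
    return pd.DataFrame(rows, index=samples, columns=list(LM22_COLUMNS))


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Full cohort: counts, clinical, fractions, and planted truth."""
    if config is None:
        config = CohortConfig()
    panel = load_default_panel()
    counts, true_clusters = generate_counts(config, panel)
    clinical = generate_clinical(
        true_clusters, config.clinical_enrichment, seed=config.seed + 1
    )
    normal_ids = [s for s in counts.samples if counts.roles[s] == "normal"]
    fractions = generate_fractions(
        true_clusters, config.fraction_shifts, seed=config.seed + 2, normal_ids=normal_ids
    )
    true_iem = {c: set(m) for c, m in config.iem_truth.items()}
    return SyntheticCohort(counts, true_clusters, true_iem, clinical, fractions, panel, config)
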