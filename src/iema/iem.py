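"""Immune evasion mechanism annotation over the cancer-immunity cycle.

A cluster's differential-expression table (cluster vs pooled adjacent
normals) is mapped onto a gene panel organized by cancer-immunity-cycle
step.  The rules:

* no cycle step shows an up-called gene -> immunologic **ignorance** (the
  tumor raises no danger signal at all);
* some step is active but antigen presentation is not, and killing or
  infiltration is also silent -> **impaired antigen presentation** / low
  CTL activation;
* any checkpoint gene set with an up-called member -> the corresponding
  **tolerance** tag (CTLA4, PD-1, PD-L1/2, TGF-beta);
* any decoy-receptor set with an up-called member -> the corresponding
  **counterattack** tag (DcR3, TRAILR4).

Tolerance and counterattack tags combine freely with ignorance or impaired
presentation; ignorance and impaired presentation are mutually exclusive
by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources as importlib_resources

import pandas as pd

__all__ = [
    "REQUIRED_STEPS",
    "CancerImmunityPanel",
    "IEMProfile",
    "load_panel",
    "load_default_panel",
    "annotate_cluster",
    "summarize_prevalence",
]

REQUIRED_STEPS = (
    "antigen_release",
    "antigen_presentation",
    "priming_activation",
    "trafficking",
    "infiltration",
    "recognition",
    "killing",
)

IGNORANCE = "ignorance"
IMPAIRED = "impaired_antigen_presentation"

# defaults for what counts as an "up-called" gene when scoring mechanisms;
# looser than the headline DE fold-change cut because checkpoint shifts
# need not be 4-fold to matter
UP_CALL_LFC = 1.0
UP_CALL_ALPHA = 0.05
MIN_STEP_GENES = 1


@dataclass
class CancerImmunityPanel:
    """Gene panel: cycle steps, checkpoint sets, decoy sets, effectors."""

    steps: dict
    checkpoint_genes: dict
    decoy_genes: dict
    effector_genes: set
    therapy_lookup: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in REQUIRED_STEPS if s not in self.steps]
        if missing:
            raise ValueError(f"panel missing required cycle steps: {missing}")
        for step, genes in self.steps.items():
            if not genes:
                raise ValueError(f"cycle step {step!r} has an empty gene set")
        overlap = set(self.checkpoint_genes) & set(self.decoy_genes)
        if overlap:
            raise ValueError(f"mechanism tags must be unique; duplicated: {overlap}")

    def all_genes(self) -> set:
        out = set()
        for genes in self.steps.values():
            out |= set(genes)
        for genes in self.checkpoint_genes.values():
            out |= set(genes)
        for genes in self.decoy_genes.values():
            out |= set(genes)
        out |= set(self.effector_genes)
        return out


@dataclass
class IEMProfile:
    """Mechanisms called for one cluster, with supporting evidence."""

    cluster: str
    mechanisms: set
    evidence: dict  # mechanism -> list of {gene, de_class, log2fc, padj} (or absence note)

    def to_dict(self) -> dict:
        return {
            "cluster": self.cluster,
            "mechanisms": sorted(self.mechanisms),
            "evidence": self.evidence,
        }


def load_panel(path) -> CancerImmunityPanel:
    """Load a panel from a JSON file of step/checkpoint/decoy gene lists."""
    with open(path) as fh:
        raw = json.load(fh)
    return CancerImmunityPanel(
        steps={k: set(v) for k, v in raw["steps"].items()},
        checkpoint_genes={k: set(v) for k, v in raw["checkpoint_genes"].items()},
        decoy_genes={k: set(v) for k, v in raw["decoy_genes"].items()},
        effector_genes=set(raw.get("effector_genes", [])),
        therapy_lookup=raw.get("therapy_lookup", {}),
    )


def load_default_panel() -> CancerImmunityPanel:
    ref = importlib_resources.files("iema") / "resources" / "cancer_immunity_panel.json"
    with importlib_resources.as_file(ref) as path:
        return load_panel(path)


def _up_called(de: pd.DataFrame, gene: str, lfc: float, alpha: float) -> bool:
    if gene not in de.index:  # missing genes are treated as not significant
        return False
    row = de.loc[gene]
    return (
        row["de_class"] in ("up", "minimal_up")
        and row["padj"] < alpha
        and row["log2fc"] > lfc
    )


def annotate_cluster(
    de: pd.DataFrame,
    panel: CancerImmunityPanel,
    cluster: str = "cluster",
    min_step_genes: int = MIN_STEP_GENES,
    up_call_lfc: float = UP_CALL_LFC,
    alpha: float = UP_CALL_ALPHA,
) -> IEMProfile:
    """Call evasion mechanisms for one cluster from its DE table."""
    if de is None or len(de) == 0:
        raise ValueError("empty DE table")

    def ev(gene):
        row = de.loc[gene]
        return {
            "gene": gene,
            "de_class": str(row["de_class"]),
            "log2fc": float(row["log2fc"]),
            "padj": float(row["padj"]),
        }

    step_hits = {
        step: [g for g in sorted(genes) if _up_called(de, g, up_call_lfc, alpha)]
        for step, genes in panel.steps.items()
    }
    active = {step for step, hits in step_hits.items() if len(hits) >= min_step_genes}

    mechanisms: set = set()
    evidence: dict = {}
    if not active:
        mechanisms.add(IGNORANCE)
        evidence[IGNORANCE] = [
            {"note": "no cancer-immunity-cycle step has an up-called gene"}
        ]
    elif "antigen_presentation" not in active and (
        "killing" not in active or "infiltration" not in active
    ):
        mechanisms.add(IMPAIRED)
        evidence[IMPAIRED] = [ev(g) for hits in step_hits.values() for g in hits]

    for tag, genes in panel.checkpoint_genes.items():
        hits = [g for g in sorted(genes) if _up_called(de, g, up_call_lfc, alpha)]
        if hits:
            mechanisms.add(tag)
            evidence[tag] = [ev(g) for g in hits]
    for tag, genes in panel.decoy_genes.items():
        hits = [g for g in sorted(genes) if _up_called(de, g, up_call_lfc, alpha)]
        if hits:
            mechanisms.add(tag)
            evidence[tag] = [ev(g) for g in hits]

    return IEMProfile(cluster=cluster, mechanisms=mechanisms, evidence=evidence)


def summarize_prevalence(
    cluster_sizes: dict,
    profiles: dict,
    denominator: int,
    queries: list | None = None,
    exact: bool = False,
) -> pd.DataFrame:
    """Prevalence of mechanism combinations over patients.

    For each queried mechanism set M, prevalence is the share of patients
    in clusters whose mechanism set contains M (or equals M when ``exact``),
    as a percentage of ``denominator``.  The empty query counts every
    cluster, i.e. the clustered fraction of the denominator.
    """
    missing = [c for c in cluster_sizes if c not in profiles]
    if missing:
        raise ValueError(f"clusters without an IEM profile: {missing}")
    total = sum(cluster_sizes.values())
    if denominator < total:
        raise ValueError("denominator must be at least the sum of cluster sizes")
    if queries is None:
        seen = set()
        queries = []
        for prof in profiles.values():
            key = frozenset(prof.mechanisms)
            if key not in seen:
                seen.add(key)
                queries.append(set(key))

    rows = []
    for q in queries:
        qs = set(q)
        if exact:
            hit = [c for c in cluster_sizes if set(profiles[c].mechanisms) == qs]
        else:
            hit = [c for c in cluster_sizes if qs <= set(profiles[c].mechanisms)]
        n = sum(cluster_sizes[c] for c in hit)
        rows.append(
            {
                "mechanisms": " & ".join(sorted(qs)) if qs else "(any)",
                "n_patients": n,
                "percent": 100.0 * n / denominator,
                "clusters": ",".join(sorted(hit)),
            }
        )
    return pd.DataFrame(rows)
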