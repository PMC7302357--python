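"""End-to-end orchestration: cluster -> DE -> annotate -> summarize.

``run_pipeline`` executes sequential plaid clustering on the tumor
samples, per-cluster NB differential expression against the pooled
adjacent normals, evasion-mechanism annotation, mechanism-prevalence
summaries, optional immune-fraction and clinical-association stages, and
the biomarker tree, writing per-stage tables plus a single JSON report.
Fully deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical as clinical_mod
from . import immune as immune_mod
from .de import de_table
from .iem import annotate_cluster, load_default_panel, load_panel, summarize_prevalence
from .io import CountMatrix, read_clinical, read_counts, read_fractions, read_gene_list
from .plaid import PlaidParams, preprocess_counts
from .sequential import sequential_cluster
from .tree import TreeParams, accuracy, extract_biomarkers, fit_cart

logger = logging.getLogger("iema")

__all__ = ["PipelineConfig", "run_pipeline", "run_pipeline_from_files"]


@dataclass
class PipelineConfig:
    counts_path: str | None = None
    gene_list_path: str | None = None
    roles_path: str | None = None
    clinical_path: str | None = None
    fractions_path: str | None = None
    panel_path: str | None = None
    output_dir: str = "iema_output"
    min_frac: float = 0.05
    plaid: PlaidParams = field(default_factory=PlaidParams)
    tree: TreeParams = field(default_factory=TreeParams)
    iem_up_call_lfc: float = 1.0
    iem_alpha: float = 0.05
    seed: int = 0

    def validate_paths(self) -> None:
        if self.counts_path is None:
            raise ValueError("counts path is required")
        for name in ("counts_path", "gene_list_path", "roles_path",
                     "clinical_path", "fractions_path", "panel_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(
    config: PipelineConfig,
    counts: CountMatrix,
    clinical: pd.DataFrame | None = None,
    fractions: pd.DataFrame | None = None,
    panel=None,
) -> dict:
    """Run every stage on in-memory inputs; write outputs; return the report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if panel is None:
        panel = load_default_panel()
    config.plaid.seed = config.seed

    report: dict = {"seed": config.seed}

    # --- sequential plaid clustering on tumors
    logger.info("stage: sequential clustering (seed=%d)", config.seed)
    tumor = counts.tumor()
    normal = counts.normal()
    Z = preprocess_counts(tumor)
    assignment = sequential_cluster(Z, config.plaid, min_frac=config.min_frac)
    labels = assignment.labels()
    pd.Series(labels, name="cluster").sort_index().to_csv(
        out / "clusters.tsv", sep="\t", index_label="sample"
    )
    (out / "clusters.json").write_text(
        json.dumps(assignment.to_dict(), indent=2, default=_jsonable)
    )
    summary = assignment.summary()
    report["clusters"] = {
        "n_total": assignment.n_total,
        "n_clustered": assignment.n_clustered,
        "pct_clustered": 100.0 * assignment.n_clustered / assignment.n_total,
        "sizes": {cid: len(s) for cid, s, _ in assignment.clusters},
        "pct_of_cohort": dict(zip(summary.get("cluster", []), summary.get("pct_of_cohort", []))),
        "pct_of_clustered": dict(zip(summary.get("cluster", []), summary.get("pct_of_clustered", []))),
        "unclustered": len(assignment.unclustered),
    }
    report["assignment"] = {s: labels[s] for s in sorted(labels)}

    # --- per-cluster DE vs pooled normals + IEM annotation
    logger.info("stage: differential expression and IEM annotation")
    profiles = {}
    de_tables = {}
    for cid, samples, _ in assignment.clusters:
        de = de_table(tumor[list(samples)], normal)
        de_tables[cid] = de
        de.to_csv(out / f"de_{cid}.tsv", sep="\t", index_label="gene")
        profiles[cid] = annotate_cluster(
            de, panel, cluster=cid,
            up_call_lfc=config.iem_up_call_lfc, alpha=config.iem_alpha,
        )
    report["iem"] = {cid: sorted(p.mechanisms) for cid, p in profiles.items()}
    (out / "iem_profiles.json").write_text(
        json.dumps({cid: p.to_dict() for cid, p in profiles.items()}, indent=2, default=_jsonable)
    )
    iem_rows = []
    for cid, p in profiles.items():
        iem_rows.append({
            "cluster": cid,
            "mechanisms": "; ".join(sorted(p.mechanisms)),
            "suggested_therapies": "; ".join(
                panel.therapy_lookup.get(m, "") for m in sorted(p.mechanisms)
            ),
        })
    pd.DataFrame(iem_rows).to_csv(out / "iem_profiles.tsv", sep="\t", index=False)

    if profiles:
        sizes = {cid: len(s) for cid, s, _ in assignment.clusters}
        prevalence = summarize_prevalence(sizes, profiles, denominator=assignment.n_clustered)
        prevalence.to_csv(out / "iem_prevalence.tsv", sep="\t", index=False)
        report["iem_prevalence"] = prevalence.to_dict(orient="records")

    # --- immune composition (optional)
    if fractions is not None:
        logger.info("stage: immune composition")
        fr = fractions.copy()
        fr["total_lymphocytes"] = [
            immune_mod.total_lymphocytes(row) for _, row in fractions.iterrows()
        ]
        cluster_labels = {s: c for s, c in labels.items() if c != "unclustered"}
        normal_samples = [s for s in counts.samples if counts.roles[s] == "normal"]
        cell_summary = immune_mod.cluster_cell_summary(fr, cluster_labels, normal_samples)
        cell_summary.to_csv(out / "immune_summary.tsv", sep="\t", index=False)
        report["immune"] = {
            "mean_total_lymphocytes_by_cluster": {
                cid: float(fr.loc[[s for s, c in cluster_labels.items() if c == cid],
                                  "total_lymphocytes"].mean())
                for cid in sorted(set(cluster_labels.values()))
            }
        }

    # --- clinical associations (optional)
    if clinical is not None and assignment.clusters:
        logger.info("stage: clinical associations")
        assoc_report = {}
        rows = []
        for variable in clinical.columns:
            try:
                results = clinical_mod.associate_clusters(assignment, clinical, variable)
            except ValueError as exc:
                logger.warning("skipping clinical variable %r: %s", variable, exc)
                continue
            assoc_report[variable] = {r.cluster: r.p for r in results}
            rows.extend(r.to_dict() for r in results)
        pd.DataFrame(rows).to_csv(out / "clinical_associations.tsv", sep="\t", index=False)
        report["clinical"] = assoc_report

    # --- biomarker tree
    if len(assignment.clusters) >= 2:
        logger.info("stage: biomarker tree")
        clustered = [s for s, c in labels.items() if c != "unclustered"]
        expr = np.log2(tumor[clustered] + 1).T  # samples x genes
        model = fit_cart(expr, {s: labels[s] for s in clustered}, config.tree)
        biomarkers = extract_biomarkers(model)
        resub = accuracy(model, expr, {s: labels[s] for s in clustered})
        (out / "tree.json").write_text(json.dumps(model.to_dict(), indent=2, default=_jsonable))
        (out / "tree.txt").write_text(model.render() + "\n")
        pd.Series(biomarkers, name="gene").to_csv(out / "biomarkers.tsv", sep="\t", index=False)
        report["tree"] = {"biomarkers": biomarkers, "resubstitution_accuracy": resub}

    report_text = json.dumps(report, indent=2, sort_keys=True, default=_jsonable)
    (out / "report.json").write_text(report_text)
    return report


def run_pipeline_from_files(config: PipelineConfig) -> dict:
    """File-based entry point: read inputs per config, then run the pipeline."""
    config.validate_paths()
    gene_list = read_gene_list(config.gene_list_path) if config.gene_list_path else None
    counts = read_counts(config.counts_path, gene_list=gene_list, roles_path=config.roles_path)
    clin = read_clinical(config.clinical_path) if config.clinical_path else None
    fr = read_fractions(config.fractions_path) if config.fractions_path else None
    panel = load_panel(config.panel_path) if config.panel_path else None
    return run_pipeline(config, counts, clinical=clin, fractions=fr, panel=panel)
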