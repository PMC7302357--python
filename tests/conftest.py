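import json

import numpy as np
import pytest

from iema.iem import load_default_panel
from iema.pipeline import PipelineConfig, run_pipeline
from iema.synthetic import CohortConfig, generate_cohort

DEFAULT_SEED = 0


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def default_cohort():
    """The default strong-signal cohort: 300 tumors, 4 planted clusters."""
    return generate_cohort(CohortConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast three-cluster cohort (100 tumors) for recovery tests."""
    cfg = CohortConfig(
        n_tumor=100,
        n_normal=12,
        n_genes=200,
        n_clusters=3,
        cluster_fracs=(0.40, 0.35, 0.25),
        genes_per_cluster=20,
        iem_truth={
            "cluster_1": {"ignorance"},
            "cluster_2": {"ignorance", "tolerance:CTLA4"},
            "cluster_3": {"ignorance", "counterattack:DcR3"},
        },
        clinical_enrichment={"cluster_2": {"gleason_cat": {"ge8": 20.0}}},
        fraction_shifts={"cluster_3": {"T cells regulatory (Tregs)": 5.0}},
        seed=DEFAULT_SEED,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def pipeline_runs(default_cohort, tmp_path_factory):
    """Two full pipeline runs on the default cohort with one seed.

    Returns (report_one, report_two, report_text_one, report_text_two, outdir).
    """
    reports = []
    texts = []
    dirs = []
    for tag in ("a", "b"):
        out = tmp_path_factory.mktemp(f"pipeline_{tag}")
        cfg = PipelineConfig(output_dir=str(out), seed=DEFAULT_SEED)
        rep = run_pipeline(
            cfg,
            default_cohort.counts,
            clinical=default_cohort.clinical,
            fractions=default_cohort.fractions,
            panel=default_cohort.panel,
        )
        reports.append(rep)
        texts.append((out / "report.json").read_text())
        dirs.append(out)
    return reports[0], reports[1], texts[0], texts[1], dirs[0]


def majority_match(members, truth):
    """Label of the true group holding the majority of ``members``."""
    groups = {}
    for s in members:
        groups[truth[s]] = groups.get(truth[s], 0) + 1
    return max(sorted(groups), key=lambda g: groups[g])
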