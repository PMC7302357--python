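"""Synthetic cohort generator: determinism, planted signal, marginal laws."""

import numpy as np
import pandas as pd
import pytest

from iema.plaid import PlaidParams, preprocess_counts
from iema.sequential import sequential_cluster
from iema.synthetic import (
    LM22_COLUMNS,
    CohortConfig,
    generate_clinical,
    generate_cohort,
    generate_counts,
    generate_fractions,
)


class TestConfig:
    def test_fracs_must_sum_to_at_most_one(self):
        with pytest.raises(ValueError, match="sum"):
            CohortConfig(n_clusters=2, cluster_fracs=(0.7, 0.6))

    def test_small_fracs_rejected_by_default(self):
        with pytest.raises(ValueError, match="allow_small_clusters"):
            CohortConfig(n_clusters=2, cluster_fracs=(0.5, 0.04))
        CohortConfig(n_clusters=2, cluster_fracs=(0.5, 0.04), allow_small_clusters=True)

    def test_dispersion_positive(self):
        with pytest.raises(ValueError, match="nb_dispersion"):
            CohortConfig(nb_dispersion=0.0)


class TestCounts:
    def test_seeded_determinism_bit_identical(self):
        a, ta = generate_counts(CohortConfig(seed=7, n_tumor=40, n_normal=6, n_genes=120,
                                             genes_per_cluster=10))
        b, tb = generate_counts(CohortConfig(seed=7, n_tumor=40, n_normal=6, n_genes=120,
                                             genes_per_cluster=10))
        assert ta == tb
        assert a.counts.equals(b.counts)
        assert a.counts.to_csv() == b.counts.to_csv()

    def test_block_fold_change_matches_planted_effect(self):
        # near-deterministic counts: block mean / baseline mean ~ 2**3
        cfg = CohortConfig(
            n_tumor=60, n_normal=6, n_genes=150, n_clusters=1, cluster_fracs=(0.5,),
            layer_effect=3.0, nb_dispersion=1e-8, genes_per_cluster=20,
            iem_truth={"cluster_1": set()}, clinical_enrichment={}, fraction_shifts={},
            base_log_mean_range=(6.0, 8.0), seed=1,
        )
        cm, truth = generate_counts(cfg)
        members = [s for s, g in truth.items() if g == "cluster_1"]
        background = [s for s, g in truth.items() if g == "background"]
        tumor = cm.tumor()
        # identify up-planted genes from the truthless side: ratio per gene
        ratio = (tumor[members].mean(axis=1) + 1) / (tumor[background].mean(axis=1) + 1)
        up = ratio[ratio > 4].index
        assert len(up) == 10  # half of the 20 signature genes are up
        assert np.allclose(ratio[up], 8.0, rtol=0.1)

    def test_normals_carry_baseline_only(self):
        cohort = generate_cohort(CohortConfig(seed=3, n_tumor=40, n_normal=20, n_genes=120,
                                              genes_per_cluster=10))
        cm = cohort.counts
        # CTLA4 is planted up in cluster_2 tumors but must stay baseline in normals
        normals = cm.normal()
        c2 = [s for s, g in cohort.true_clusters.items() if g == "cluster_2"]
        ratio = cm.counts.loc["CTLA4", c2].mean() / max(normals.loc["CTLA4"].mean(), 1)
        assert ratio > 4

    def test_counts_are_non_negative_integers(self):
        cm, _ = generate_counts(CohortConfig(seed=2, n_tumor=30, n_normal=4, n_genes=120,
                                             genes_per_cluster=10))
        assert (cm.counts.to_numpy() >= 0).all()
        assert np.issubdtype(cm.counts.to_numpy().dtype, np.integer)

    def test_null_effect_yields_no_clusters_in_most_seeds(self):
        hits = 0
        for seed in range(10):
            cfg = CohortConfig(n_tumor=80, n_normal=10, n_genes=150, layer_effect=0.0,
                               genes_per_cluster=10, seed=seed)
            cohort = generate_cohort(cfg)
            Z = preprocess_counts(cohort.counts.tumor())
            assignment = sequential_cluster(Z, PlaidParams(seed=seed), min_frac=0.05)
            hits += len(assignment.clusters) == 0
        assert hits >= 9


class TestClinical:
    def truth(self, n=60):
        half = n // 2
        return {f"T{i:03d}": ("cluster_1" if i < half else "background") for i in range(n)}

    def test_null_multipliers_match_baseline(self):
        # frequencies within 3 sigma of the baseline simplex
        truth = {f"T{i:04d}": "background" for i in range(2000)}
        clin = generate_clinical(truth, {}, seed=0)
        from iema.synthetic import GLEASON_BASELINE

        for cat, p in GLEASON_BASELINE.items():
            obs = (clin["gleason_cat"] == cat).mean()
            sigma = np.sqrt(p * (1 - p) / len(truth))
            assert abs(obs - p) <= 3 * sigma

    def test_enriched_cluster_detected_by_exact_test(self):
        from iema.clinical import associate_clusters
        from iema.sequential import ClusterAssignment

        truth = self.truth(120)
        clin = generate_clinical(
            truth, {"cluster_1": {"gleason_cat": {"ge8": 20.0}}}, seed=5
        )
        groups = {}
        for s, g in truth.items():
            groups.setdefault(g, []).append(s)
        assignment = ClusterAssignment(
            [(g, list(ss), []) for g, ss in groups.items()], [], 120, 0.05
        )
        results = associate_clusters(assignment, clin, "gleason_cat")
        p1 = next(r.p for r in results if r.cluster == "cluster_1")
        assert p1 < 0.01

    def test_unknown_cluster_or_category_errors(self):
        truth = self.truth()
        with pytest.raises(ValueError, match="unknown cluster"):
            generate_clinical(truth, {"nope": {}}, seed=0)
        with pytest.raises(ValueError, match="unknown category"):
            generate_clinical(truth, {"cluster_1": {"gleason_cat": {"g11": 2.0}}}, seed=0)

    def test_deterministic(self):
        truth = self.truth()
        a = generate_clinical(truth, {}, seed=4)
        b = generate_clinical(truth, {}, seed=4)
        assert a.equals(b)


class TestFractions:
    def truth(self, n=50):
        return {f"T{i:03d}": ("cluster_1" if i < n // 2 else "background") for i in range(n)}

    def test_rows_sum_to_one(self):
        fr = generate_fractions(self.truth(), {}, seed=0)
        assert np.allclose(fr.sum(axis=1), 1.0, atol=1e-9)
        assert list(fr.columns) == list(LM22_COLUMNS)

    def test_uniform_concentration_symmetric_means(self):
        fr = generate_fractions({f"T{i:04d}": "background" for i in range(3000)}, {}, seed=1)
        k = len(LM22_COLUMNS)
        # Dirichlet(2,...,2): var of one coordinate = (1/k)(1-1/k)/(2k+1);
        # 4 sigma keeps the joint test over 22 columns at ~0.1% false alarm
        sigma = np.sqrt((1 / k) * (1 - 1 / k) / (2 * k + 1) / len(fr))
        assert np.all(np.abs(fr.mean(axis=0) - 1 / k) <= 4 * sigma)

    def test_treg_shift_raises_mean_in_most_seeds(self):
        wins = 0
        for seed in range(20):
            fr = generate_fractions(
                self.truth(100),
                {"cluster_1": {"T cells regulatory (Tregs)": 5.0}},
                seed=seed,
            )
            shifted = fr.iloc[:50]["T cells regulatory (Tregs)"].mean()
            base = fr.iloc[50:]["T cells regulatory (Tregs)"].mean()
            wins += shifted > base
        assert wins >= 19  # >= 95% of seeds

    def test_invalid_concentrations_error(self):
        with pytest.raises(ValueError, match="unknown LM22"):
            generate_fractions(self.truth(), {"cluster_1": {"Tregs": 2.0}}, seed=0)
        with pytest.raises(ValueError, match="positive"):
            generate_fractions(self.truth(), {"cluster_1": {"T cells CD8": -1.0}}, seed=0)


def test_cohort_writes_plain_text_bundle(tmp_path, small_cohort):
    small_cohort.write(tmp_path)
    for name in ("counts.tsv", "sample_roles.tsv", "clinical.tsv", "fractions.csv", "truth.json"):
        assert (tmp_path / name).exists()
    import json

    truth = json.loads((tmp_path / "truth.json").read_text())
    assert set(truth["true_iem"]) == set(small_cohort.true_iem)


def test_cohort_determinism_byte_identical_serialization(tmp_path):
    cfg = dict(seed=9, n_tumor=40, n_normal=6, n_genes=120, genes_per_cluster=10)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    generate_cohort(CohortConfig(**cfg)).write(d1)
    generate_cohort(CohortConfig(**cfg)).write(d2)
    for name in ("counts.tsv", "clinical.tsv", "fractions.csv", "truth.json"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
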