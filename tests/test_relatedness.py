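"""IBS distances, kinship clustering, subgroup calls, crossing patterns."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from heteroscan.panel import MISSING
from heteroscan.relatedness import (
    DistanceMatrix,
    classify_subgroup,
    crossing_pattern_counts,
    ibs_distance_matrix,
    kinship_clusters,
    kinship_matrix,
    parental_distance_summary,
)
from heteroscan.synthetic import generate_hybrid_table

from .conftest import make_accessions, make_hybrids, make_panel


class TestIbsDistance:
    def test_trivial_pairs(self):
        calls = np.array(
            [[0, 2, 1, 0], [0, 2, 1, 0], [2, 0, 1, 2], [1, 1, 0, 1]], dtype=np.int8
        )
        dist = ibs_distance_matrix(make_panel(calls))
        assert dist.pair("acc00", "acc01") == 0.0  # identical
        assert dist.pair("acc00", "acc02") == pytest.approx(0.75)  # 3 of 4 opposite
        # het vs hom at every site -> 0.5
        assert dist.pair("acc02", "acc03") == 0.5

    def test_opposite_homozygotes_distance_one(self):
        calls = np.array([[0, 0, 0], [2, 2, 2]], dtype=np.int8)
        assert ibs_distance_matrix(make_panel(calls)).pair("acc00", "acc01") == 1.0

    def test_missing_sites_excluded_from_mean(self):
        calls = np.array([[0, 0, MISSING], [2, 0, 2]], dtype=np.int8)
        # only first two sites co-called: (1 + 0) / 2
        assert ibs_distance_matrix(make_panel(calls)).pair("acc00", "acc01") == 0.5

    def test_metric_properties_on_random_panels(self):
        rng = np.random.default_rng(5)
        calls = rng.choice([0, 1, 2], size=(12, 200)).astype(np.int8)
        dist = ibs_distance_matrix(make_panel(calls))
        m = dist.matrix
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0.0)
        assert ((m >= 0) & (m <= 1)).all()
        for i, j, k in [(0, 1, 2), (3, 7, 11), (2, 5, 9), (1, 8, 4)]:
            assert m[i, k] <= m[i, j] + m[j, k] + 1e-12

    def test_zero_call_accession_flagged(self):
        calls = np.array([[0, 2], [MISSING, MISSING]], dtype=np.int8)
        dist = ibs_distance_matrix(make_panel(calls))
        assert dist.no_call_accessions == ["acc01"]
        assert np.isnan(dist.pair("acc00", "acc01"))


def welch_p(x, y):
    """Independent hand-coded two-tailed Welch t-test."""
    nx, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    t = (np.mean(x) - np.mean(y)) / math.sqrt(vx / nx + vy / ny)
    df = (vx / nx + vy / ny) ** 2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    )
    return 2 * stats.t.sf(abs(t), df)


class TestParentalDistances:
    def test_single_pair_mean(self):
        matrix = np.array([[0.0, 0.3], [0.3, 0.0]])
        dist = DistanceMatrix(ids=["a", "b"], matrix=matrix)
        summary = parental_distance_summary(dist, {"set1": make_hybrids([("a", "b")])})
        row = summary[summary["set"] == "set1"].iloc[0]
        assert row["mean"] == 0.3 and row["n"] == 1

    def test_background_pair_count_formula(self):
        n = 1143
        ids = [f"a{i}" for i in range(n)]
        dist = DistanceMatrix(ids=ids, matrix=np.zeros((n, n)))
        summary = parental_distance_summary(dist, {})
        assert summary.iloc[0]["n"] == n * (n - 1) // 2 == 652_653

    def test_welch_p_matches_independent_implementation(self):
        rng = np.random.default_rng(13)
        n = 40
        ids = [f"a{i}" for i in range(n)]
        matrix = np.abs(rng.normal(0.3, 0.05, (n, n)))
        matrix = (matrix + matrix.T) / 2
        np.fill_diagonal(matrix, 0.0)
        # hybrid parents drawn apart by construction: inflate their distances
        pairs = [(ids[i], ids[i + 20]) for i in range(10)]
        for f, m in pairs:
            i, j = ids.index(f), ids.index(m)
            matrix[i, j] = matrix[j, i] = matrix[i, j] + 0.2
        dist = DistanceMatrix(ids=ids, matrix=matrix)
        summary = parental_distance_summary(dist, {"sup": make_hybrids(pairs)})
        p_reported = summary[summary["set"] == "sup"].iloc[0]["welch_p_vs_background"]
        values = np.array([dist.pair(f, m) for f, m in pairs])
        background = dist.condensed()
        assert p_reported == pytest.approx(welch_p(values, background), rel=1e-9)
        assert p_reported < 0.01

    def test_empty_set_rejected(self):
        dist = DistanceMatrix(ids=["a", "b"], matrix=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="empty"):
            parental_distance_summary(dist, {"bad": make_hybrids([])})


class TestKinship:
    def test_duplicated_accessions_share_coefficients(self):
        rng = np.random.default_rng(3)
        base = rng.choice([0, 2], size=200).astype(np.int8)
        other = rng.choice([0, 2], size=200).astype(np.int8)
        k = kinship_matrix(make_panel(np.stack([base, base, other])))
        assert k[0, 1] == pytest.approx(k[0, 0])
        assert k[0, 1] == pytest.approx(k[1, 1])

    def test_mirror_coded_pair_negative(self):
        calls = np.array([[0, 0, 2, 2], [2, 2, 0, 0]], dtype=np.int8)
        k = kinship_matrix(make_panel(calls))
        assert k[0, 1] < 0

    def test_positive_semidefinite_on_random_panels(self):
        rng = np.random.default_rng(7)
        for trial in range(3):
            calls = rng.choice([0, 1, 2, MISSING], size=(15, 300), p=[0.45, 0.05, 0.45, 0.05])
            k = kinship_matrix(make_panel(calls.astype(np.int8)))
            assert np.linalg.eigvalsh(k).min() >= -1e-8

    def test_monomorphic_panel_rejected(self):
        with pytest.raises(ValueError, match="polymorphic"):
            kinship_matrix(make_panel(np.zeros((4, 10), dtype=np.int8)))

    def test_parent_offspring_half_of_self(self):
        """Simulated matings: mean parent-offspring coefficient is half the
        mean self-coefficient (within Monte-Carlo error)."""
        rng = np.random.default_rng(19)
        n_parents, n_sites = 60, 3000
        freqs = rng.uniform(0.1, 0.9, n_sites)
        parents = (rng.random((n_parents, n_sites)) < freqs).astype(np.int8) * 2
        pairs = [(2 * i, 2 * i + 1) for i in range(n_parents // 2)]
        # inbred parents: child dosage = maternal allele + paternal allele
        children = np.stack(
            [(parents[a] // 2 + parents[b] // 2) for a, b in pairs]
        ).astype(np.int8)
        panel = make_panel(np.vstack([parents, children]))
        k = kinship_matrix(panel)
        self_mean = np.diag(k)[:n_parents].mean()
        po = [k[a, n_parents + ci] for ci, (a, b) in enumerate(pairs)]
        assert np.mean(po) / self_mean == pytest.approx(0.5, abs=0.05)


class TestKinshipClusters:
    def test_no_edges_all_singletons(self):
        k = np.zeros((4, 4))
        graph = kinship_clusters(k, ["a", "b", "c", "d"])
        assert graph.clusters == [] and len(graph.singletons) == 4

    def test_chain_forms_single_cluster(self):
        k = np.zeros((3, 3))
        k[0, 1] = k[1, 0] = 0.6
        k[1, 2] = k[2, 1] = 0.5
        graph = kinship_clusters(k, ["a", "b", "c"], threshold=0.45)
        assert graph.clusters == [["a", "b", "c"]]
        assert graph.n_relationships == 2

    def test_two_disjoint_pairs(self):
        k = np.zeros((5, 5))
        k[0, 1] = k[1, 0] = 0.7
        k[2, 3] = k[3, 2] = 0.5
        graph = kinship_clusters(k, list("abcde"))
        assert len(graph.clusters) == 2 and graph.singletons == ["e"]

    def test_threshold_is_strict(self):
        k = np.zeros((2, 2))
        k[0, 1] = k[1, 0] = 0.45
        assert kinship_clusters(k, ["a", "b"], threshold=0.45).n_relationships == 0

    def test_cluster_singleton_partition(self):
        rng = np.random.default_rng(23)
        n = 20
        k = rng.uniform(0, 0.6, (n, n))
        k = (k + k.T) / 2
        ids = [f"a{i}" for i in range(n)]
        graph = kinship_clusters(k, ids)
        members = [a for c in graph.clusters for a in c] + graph.singletons
        assert sorted(members) == sorted(ids)


class TestClassifySubgroup:
    def test_identical_to_reference(self):
        calls = np.array([[0, 2, 0], [2, 0, 2], [0, 2, 0]], dtype=np.int8)
        labels = classify_subgroup(make_panel(calls), "acc00", "acc01", tie_band=0.0)
        assert labels["acc02"] == "IndI"

    def test_equidistant_unassigned(self):
        calls = np.array([[0, 0], [2, 2], [0, 2]], dtype=np.int8)
        labels = classify_subgroup(make_panel(calls), "acc00", "acc01")
        assert labels["acc02"] == "unassigned"

    def test_recovery_at_default_divergence(self, default_panel):
        """>= 95% of accessions recover their generating subgroup at
        divergence 0.3, using one anchor accession per subgroup."""
        panel, accessions, _, _ = default_panel
        table = accessions.table
        ref_I = table.loc[table["subgroup"] == "IndI", "id"].iloc[0]
        ref_II = table.loc[table["subgroup"] == "IndII", "id"].iloc[0]
        labels = classify_subgroup(panel, ref_I, ref_II)
        truth = table.set_index("id")["subgroup"]
        correct = (labels == truth.loc[labels.index]).mean()
        assert correct >= 0.95


class TestCrossingPatterns:
    LABELS = {"r1": "IndII", "r2": "IndII", "s1": "IndI", "s2": "IndI"}

    def test_single_cell(self):
        hybrids = make_hybrids([("s1", "r1"), ("s2", "r2"), ("s1", "r2")])
        counts = crossing_pattern_counts(hybrids, self.LABELS)
        assert counts.loc["IndII", "IndI"] == 3
        assert counts.to_numpy().sum() == 3

    def test_empty_set_all_zero(self):
        counts = crossing_pattern_counts(make_hybrids([]), self.LABELS)
        assert counts.to_numpy().sum() == 0

    def test_unlabelled_parents_fall_in_unassigned(self):
        hybrids = make_hybrids([("s1", "mystery")])
        counts = crossing_pattern_counts(hybrids, self.LABELS)
        assert counts.loc["unassigned", "IndI"] == 1

    def test_generated_pattern_fractions_within_multinomial_bounds(self, default_panel):
        _, accessions, _, _ = default_panel
        weights = {("IndII", "IndI"): 0.9, ("IndII", "IndII"): 0.1}
        n, n_reps = 200, 5
        total = None
        for seed in range(n_reps):
            hybrids = generate_hybrid_table(
                accessions, n, 0, pattern_weights=weights, seed=seed
            ).subset(system="3-line")
            counts = crossing_pattern_counts(hybrids, accessions.subgroup_of())
            total = counts if total is None else total + counts
        assert total.to_numpy().sum() == n * n_reps
        for (r, s), w in weights.items():
            lo, hi = stats.binom.ppf([0.005, 0.995], n * n_reps, w)
            assert lo <= total.loc[r, s] <= hi
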