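"""Community detection, consensus clustering and node metrics."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from plastnet import (ConnectivityMatrix, ModulePartition, RegionVector,
                      consensus_partition, hubness_scores, louvain_partition,
                      modularity_score, node_strength,
                      participation_coefficient, planted_block_matrix,
                      within_module_connectivity)
from conftest import random_symmetric_matrix
from oracles import (brute_modularity, brute_participation,
                     brute_within_module, set_partitions)


class TestLouvain:
    def test_two_disconnected_cliques_recovered(self, two_cliques):
        part = louvain_partition(two_cliques, gamma=1.0, seed=0)
        assert part.n_modules == 2
        assert len(set(part.labels[:4])) == 1
        assert len(set(part.labels[4:])) == 1
        assert part.Q == pytest.approx(0.5, abs=1e-12)

    def test_large_gamma_gives_singletons(self, two_cliques):
        part = louvain_partition(two_cliques, gamma=10.0, seed=0)
        assert part.n_modules == 8

    def test_deterministic_given_seed(self, rng):
        cm = random_symmetric_matrix(20, rng)
        a = louvain_partition(cm, 1.0, seed=5)
        b = louvain_partition(cm, 1.0, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.Q == b.Q

    def test_best_of_restarts_attains_enumeration_maximum(self, rng):
        """Best Q over seeded restarts equals the global maximum found by
        exhaustively enumerating all partitions of an 8-node graph."""
        parts = list(set_partitions(8))
        for _ in range(5):
            cm = random_symmetric_matrix(8, rng)
            best = max(brute_modularity(cm.weights, p) for p in parts)
            lou = max(louvain_partition(cm, 1.0, seed=s).Q
                      for s in range(100))
            assert lou == pytest.approx(best, abs=1e-10)

    def test_all_zero_positive_part_single_module(self):
        W = -0.5 * np.ones((4, 4))
        np.fill_diagonal(W, 1.0)
        cm = ConnectivityMatrix(W, list("abcd"))
        with pytest.warns(UserWarning, match="single module"):
            part = louvain_partition(cm, 1.0, seed=0)
        assert part.n_modules == 1

    def test_q_not_below_singleton_start(self, rng):
        cm = random_symmetric_matrix(12, rng)
        singletons = ModulePartition(np.arange(1, 13))
        q0 = modularity_score(cm, singletons, 1.0)
        part = louvain_partition(cm, 1.0, seed=3)
        assert part.Q >= q0 - 1e-12


class TestModularityScore:
    def test_single_module_closed_form(self, two_cliques):
        one = ModulePartition(np.ones(8, int))
        for gamma in (0.8, 1.0, 1.4):
            q = modularity_score(two_cliques, one, gamma)
            assert q == pytest.approx(1.0 - gamma, abs=1e-12)

    def test_two_block_closed_form(self, two_cliques):
        nat = ModulePartition(np.array([1] * 4 + [2] * 4))
        for gamma in (0.8, 1.0, 1.4):
            q = modularity_score(two_cliques, nat, gamma)
            assert q == pytest.approx(1.0 - gamma / 2, abs=1e-12)

    def test_matches_double_sum_oracle(self, rng):
        for _ in range(5):
            cm = random_symmetric_matrix(10, rng, signed=True)
            labels = rng.integers(1, 4, size=10)
            part = ModulePartition(labels)
            q = modularity_score(cm, part, 1.1)
            # oracle must see the same (contiguous-relabelled) partition
            assert q == pytest.approx(
                brute_modularity(cm.weights, part.labels, 1.1), abs=1e-10)


class TestConsensus:
    def test_single_rep_equals_single_run(self, rng):
        cm = random_symmetric_matrix(15, rng)
        cons = consensus_partition(cm, 1.0, n_reps=1, seed=9)
        assert cons.n_modules >= 1
        assert np.isfinite(cons.Q)

    def test_deterministic_graph_binary_coassignment(self, two_cliques):
        cons = consensus_partition(two_cliques, 1.0, n_reps=20, seed=0)
        assert adjusted_rand_score(cons.labels,
                                   [1] * 4 + [2] * 4) == 1.0

    def test_planted_blocks_recovered(self):
        cm, truth = planted_block_matrix((20, 20, 19, 19), 0.6, 0.1, 0.05,
                                         seed=11)
        cons = consensus_partition(cm, 1.0, n_reps=100, seed=1)
        assert adjusted_rand_score(truth.labels, cons.labels) == 1.0

    def test_permutation_equivariance(self, rng):
        cm, _ = planted_block_matrix((6, 5, 5), 0.7, 0.1, 0.03, seed=2)
        perm = rng.permutation(16)
        ids_p = [cm.region_ids[i] for i in perm]
        cm_p = ConnectivityMatrix(cm.weights[np.ix_(perm, perm)], ids_p)
        a = consensus_partition(cm, 1.0, n_reps=50, seed=5)
        b = consensus_partition(cm_p, 1.0, n_reps=50, seed=5)
        assert adjusted_rand_score(a.labels[perm], b.labels) == 1.0


class TestNodeMetrics:
    def test_strength_complete_unit_graph_and_zero(self):
        W = np.ones((4, 4))
        cm = ConnectivityMatrix(W, list("abcd"))
        np.testing.assert_allclose(node_strength(cm).values, 3.0)
        zero = ConnectivityMatrix(np.zeros((4, 4)), list("abcd"),
                                  diagonal_policy="zeroed")
        np.testing.assert_allclose(node_strength(zero).values, 0.0)

    def test_strength_is_row_sum(self, rng):
        cm = random_symmetric_matrix(9, rng, signed=True)
        expected = cm.weights.sum(axis=1) - np.diag(cm.weights)
        np.testing.assert_allclose(node_strength(cm).values, expected,
                                   atol=1e-12)

    def test_participation_provincial_and_even_split(self):
        # region 0: all weight inside its module -> P = 0
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.8
        cm = ConnectivityMatrix(W, list("abcd"), diagonal_policy="zeroed")
        part = ModulePartition(np.array([1, 1, 2, 2]))
        P = participation_coefficient(cm, part)
        assert P.values[0] == pytest.approx(0.0, abs=1e-12)
        # equal split across 2 modules -> P = 0.5
        W2 = np.zeros((3, 3))
        W2[0, 1] = W2[1, 0] = 0.4
        W2[0, 2] = W2[2, 0] = 0.4
        cm2 = ConnectivityMatrix(W2, list("abc"), diagonal_policy="zeroed")
        part2 = ModulePartition(np.array([1, 1, 2]))
        assert participation_coefficient(cm2, part2).values[0] == \
            pytest.approx(0.5, abs=1e-12)

    def test_participation_matches_brute_force(self, rng):
        cm = random_symmetric_matrix(10, rng, signed=True)
        labels = rng.integers(1, 4, size=10)
        part = ModulePartition(labels)
        got = participation_coefficient(cm, part).values
        np.testing.assert_allclose(
            got, brute_participation(cm.weights, part.labels), atol=1e-10)

    def test_participation_upper_bound(self, rng):
        cm = random_symmetric_matrix(12, rng)
        labels = rng.integers(1, 4, size=12)
        part = ModulePartition(labels)
        P = participation_coefficient(cm, part).values
        assert np.all(P >= -1e-12)
        assert np.all(P <= 1.0 - 1.0 / part.n_modules + 1e-12)

    def test_within_between_strength_accounting(self, rng):
        """Positive within-module + between-module weight sums equal the
        positive node strength."""
        cm = random_symmetric_matrix(10, rng, signed=True)
        labels = rng.integers(1, 4, size=10)
        Wp = np.clip(cm.off_diagonal(), 0, None)
        same = labels[:, None] == labels[None, :]
        np.fill_diagonal(same, False)
        within = (Wp * same).sum(axis=1)
        between = (Wp * ~same).sum(axis=1) - np.diag(Wp)
        np.testing.assert_allclose(within + between, Wp.sum(axis=1),
                                   atol=1e-12)

    def test_within_module_constant_neighbourhood_and_singleton(self):
        W = np.zeros((5, 5))
        for j in (1, 2, 3):
            W[0, j] = W[j, 0] = 0.6
        cm = ConnectivityMatrix(W, list("abcde"), diagonal_policy="zeroed")
        part = ModulePartition(np.array([1, 1, 1, 1, 2]))
        wm = within_module_connectivity(cm, part)
        assert wm.values[0] == pytest.approx(0.6, abs=1e-12)
        assert np.isnan(wm.values[4])  # singleton module

    def test_within_module_matches_masked_mean_oracle(self, rng):
        cm = random_symmetric_matrix(11, rng, signed=True)
        labels = rng.integers(1, 5, size=11)
        part = ModulePartition(labels)
        got = within_module_connectivity(cm, part).values
        exp = brute_within_module(cm.weights, part.labels)
        np.testing.assert_allclose(got, exp, atol=1e-10, equal_nan=True)


class TestHubness:
    def test_collinear_inputs_explain_all_variance(self, rng):
        s = RegionVector(rng.standard_normal(30))
        p = RegionVector(2.5 * s.values + 3.0)
        hub, var = hubness_scores(s, p)
        assert var == pytest.approx(100.0, abs=1e-9)
        z = (s.values - s.values.mean()) / s.values.std(ddof=1)
        ratio = hub.values / z
        assert np.allclose(ratio, ratio[0]) and ratio[0] > 0

    def test_uncorrelated_columns_split_variance(self, rng):
        n = 40
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        b = b - a * (a @ b) / (a @ a)  # exactly orthogonal to a
        a, b = a - a.mean(), b - b.mean()
        b = b - a * (a @ b) / (a @ a)
        _, var = hubness_scores(RegionVector(a), RegionVector(b))
        assert var == pytest.approx(50.0, abs=1e-9)

    def test_matches_eigendecomposition_oracle(self):
        s = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        p = np.array([0.2, 0.1, 0.5, 0.4, 0.6])
        hub, var = hubness_scores(RegionVector(s), RegionVector(p))
        zs = (s - s.mean()) / s.std(ddof=1)
        zp = (p - p.mean()) / p.std(ddof=1)
        r = np.corrcoef(zs, zp)[0, 1]
        lam1 = 1 + abs(r)  # eigenvalues of [[1, r], [r, 1]]
        assert var == pytest.approx(100 * lam1 / 2, abs=1e-10)
        v = np.array([1.0, np.sign(r)]) / np.sqrt(2)
        expected = np.column_stack([zs, zp]) @ v
        if expected @ zs < 0:
            expected = -expected
        np.testing.assert_allclose(hub.values, expected, atol=1e-10)

    def test_invariant_to_affine_rescaling(self, rng):
        s = RegionVector(rng.standard_normal(25))
        p = RegionVector(rng.standard_normal(25))
        h1, v1 = hubness_scores(s, p)
        h2, v2 = hubness_scores(RegionVector(7 * s.values - 2), p)
        np.testing.assert_allclose(h1.values, h2.values, atol=1e-10)
        assert v1 == pytest.approx(v2, abs=1e-10)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            hubness_scores(RegionVector(np.ones(5)),
                           RegionVector(np.arange(5.0)))
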