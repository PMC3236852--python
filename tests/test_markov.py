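"""BNp Markov-chain machinery: TPMs, SSDs, and rank-one mutation updates."""

import itertools

import numpy as np
import pytest

from bnfault.markov import (build_H, build_tpm, deterministic_tpm,
                            fundamental_matrix, mutated_tpm, network_ssd,
                            rank_one_decompose, ssd_after_mutation,
                            ssd_after_path, ssd_rank_one_update,
                            stationary_distribution, transformation_matrix)
from bnfault.networks import BooleanNetwork, random_network
from .conftest import power_iteration_ssd


def identity_network(n):
    return BooleanNetwork(n, tuple((i,) for i in range(n)),
                          tuple(((0, 1),) * n))


class TestPerturbationMatrix:
    def test_single_gene_flip(self):
        H = build_H(1, 0.1)
        np.testing.assert_allclose(H, [[0.0, 0.1], [0.1, 0.0]])

    @pytest.mark.parametrize("n,p", [(2, 0.05), (4, 0.01), (6, 0.3), (8, 0.001)])
    def test_row_sums_are_flip_probability(self, n, p):
        H = build_H(n, p)
        np.testing.assert_allclose(H.sum(axis=1), 1.0 - (1.0 - p) ** n,
                                   atol=1e-12)

    def test_symmetric_and_zero_diagonal(self):
        H = build_H(5, 0.2)
        assert np.array_equal(H, H.T)
        assert np.all(np.diag(H) == 0.0)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_p_rejected(self, p):
        with pytest.raises(ValueError):
            build_H(2, p)


class TestTransitionMatrix:
    def test_single_gene_identity_chain(self):
        P = build_tpm(identity_network(1), 0.1)
        np.testing.assert_allclose(P, [[0.9, 0.1], [0.1, 0.9]])

    def test_q_rows_have_one_one(self, rng):
        for _ in range(10):
            Q = deterministic_tpm(random_network(4, 2, 0.5, rng))
            assert np.all(Q.sum(axis=1) == 1.0)
            assert np.all((Q == 0) | (Q == 1))

    def test_row_stochastic_random_cases(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 7))
            p = float(rng.uniform(0.001, 0.4))
            P = build_tpm(random_network(n, min(2, n), 0.3, rng), p)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert P.min() >= 0.0


class TestStationaryDistribution:
    def test_symmetric_two_state_chain(self):
        pi = stationary_distribution(build_tpm(identity_network(1), 0.1))
        np.testing.assert_allclose(pi, [0.5, 0.5], atol=1e-12)

    def test_doubly_stochastic_gives_uniform(self):
        P = np.array([[0.2, 0.5, 0.3], [0.5, 0.3, 0.2], [0.3, 0.2, 0.5]])
        np.testing.assert_allclose(stationary_distribution(P), np.ones(3) / 3,
                                   atol=1e-12)

    def test_agrees_with_power_iteration(self, rng):
        for _ in range(10):
            P = build_tpm(random_network(3, 2, 0.4, rng), 0.05)
            pi = stationary_distribution(P)
            np.testing.assert_allclose(pi, power_iteration_ssd(P), atol=1e-8)
            assert pi.min() > 0.0
            assert abs(pi.sum() - 1.0) < 1e-12


class TestTransformationMatrix:
    def test_stuck_at_zero_on_last_gene_shifts_odd_states(self):
        # forcing x_3 = 0 maps every odd state index to index - 1
        T = transformation_matrix(3, (2, 0))
        for s in range(8):
            dest = s - 1 if s % 2 else s
            assert T[s, dest] == 1.0
            assert T[s].sum() == 1.0

    def test_idempotent(self):
        T = transformation_matrix(4, (1, 1))
        np.testing.assert_array_equal(T @ T, T)

    def test_qt_equals_truth_table_mutation(self, rng):
        for _ in range(20):
            net = random_network(3, 2, 0.5, rng)
            gene, value = int(rng.integers(3)), int(rng.integers(2))
            Q = deterministic_tpm(net)
            T = transformation_matrix(3, (gene, value))
            Q_mut = deterministic_tpm(net.apply_mutation((gene, value)))
            np.testing.assert_array_equal(Q @ T, Q_mut)

    def test_rank_of_change_bounded(self, rng):
        T = transformation_matrix(3, (2, 0))
        for _ in range(20):
            Q = deterministic_tpm(random_network(3, 2, 0.5, rng))
            assert np.linalg.matrix_rank(Q @ (T - np.eye(8))) <= 4


class TestMutatedTpm:
    def test_identity_transformation_is_noop(self, rng):
        net = random_network(3, 2, 0.5, rng)
        Q = deterministic_tpm(net)
        P = build_tpm(net, 0.01)
        np.testing.assert_allclose(mutated_tpm(Q, np.eye(8), 3, 0.01), P,
                                   atol=1e-15)

    def test_equals_rebuilt_tpm(self, rng):
        for _ in range(20):
            net = random_network(4, 2, 0.5, rng)
            gene, value = int(rng.integers(4)), int(rng.integers(2))
            Q = deterministic_tpm(net)
            T = transformation_matrix(4, (gene, value))
            direct = build_tpm(net.apply_mutation((gene, value)), 0.01)
            np.testing.assert_array_equal(mutated_tpm(Q, T, 4, 0.01), direct)

    def test_threefold_mutation_composes(self, rng):
        net = random_network(4, 2, 0.5, rng)
        muts = [(0, 0), (2, 1), (3, 0)]
        Q = deterministic_tpm(net)
        T = np.eye(16)
        for m in muts:
            T = T @ transformation_matrix(4, m)
        direct = build_tpm(net.apply_path(muts), 0.01)
        np.testing.assert_allclose(mutated_tpm(Q, T, 4, 0.01), direct,
                                   atol=1e-15)


class TestRankOneDecomposition:
    def test_term_count_bounded_and_b_orthogonal_to_ones(self, rng):
        for _ in range(20):
            net = random_network(3, 2, 0.5, rng)
            Q = deterministic_tpm(net)
            T = transformation_matrix(3, (int(rng.integers(3)), int(rng.integers(2))))
            terms = rank_one_decompose(Q, T, 3, 0.01)
            assert len(terms) <= 4
            for _, b in terms:
                assert abs(b.sum()) == 0.0

    def test_reconstructs_tpm_change(self, rng):
        for _ in range(20):
            net = random_network(4, 2, 0.5, rng)
            gene, value = int(rng.integers(4)), int(rng.integers(2))
            Q = deterministic_tpm(net)
            T = transformation_matrix(4, (gene, value))
            delta = mutated_tpm(Q, T, 4, 0.01) - build_tpm(net, 0.01)
            total = sum(np.outer(a, b) for a, b in
                        rank_one_decompose(Q, T, 4, 0.01))
            np.testing.assert_allclose(total, delta, atol=1e-15)

    def test_already_satisfied_mutation_has_no_terms(self):
        # constant-zero network: every destination already has x_i = 0
        net = BooleanNetwork(3, tuple((i,) for i in range(3)),
                             tuple(((0, 0),) * 3))
        Q = deterministic_tpm(net)
        T = transformation_matrix(3, (1, 0))
        assert rank_one_decompose(Q, T, 3, 0.01) == []


class TestSsdUpdates:
    def test_zero_perturbation_keeps_ssd(self, rng):
        net = random_network(3, 2, 0.5, rng)
        P = build_tpm(net, 0.05)
        pi = stationary_distribution(P)
        b = np.zeros(8)
        b[0], b[1] = 1.0, -1.0
        np.testing.assert_array_equal(
            ssd_rank_one_update(pi, P, np.zeros(8), b), pi)

    @pytest.mark.parametrize("n", [3, 6])
    def test_single_term_matches_direct_solve(self, n, rng):
        for _ in range(10):
            net = random_network(n, 2, 0.5, rng)
            Q = deterministic_tpm(net)
            T = transformation_matrix(n, (int(rng.integers(n)),
                                          int(rng.integers(2))))
            terms = rank_one_decompose(Q, T, n, 0.01)
            if not terms:
                continue
            P = build_tpm(net, 0.01)
            pi = stationary_distribution(P)
            a, b = terms[0]
            expected = stationary_distribution(P + np.outer(a, b))
            np.testing.assert_allclose(ssd_rank_one_update(pi, P, a, b),
                                       expected, atol=1e-10)

    def test_mutation_on_constant_gene_keeps_ssd(self):
        net = BooleanNetwork(3, tuple((i,) for i in range(3)),
                             tuple(((0, 0),) * 3))
        pi = network_ssd(net, 0.05)
        np.testing.assert_allclose(ssd_after_mutation(net, 0.05, pi, (1, 0)),
                                   pi, atol=1e-12)

    def test_sequential_updates_match_direct_solve(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 7))
            net = random_network(n, 2, 0.4, rng)
            m = (int(rng.integers(n)), int(rng.integers(2)))
            pi = network_ssd(net, 0.01)
            via_updates = ssd_after_mutation(net, 0.01, pi, m)
            direct = network_ssd(net.apply_mutation(m), 0.01)
            np.testing.assert_allclose(via_updates, direct, atol=1e-9)
            assert abs(via_updates.sum() - 1.0) < 1e-9

    def test_path_ssd_is_order_free(self, rng):
        for _ in range(5):
            net = random_network(4, 2, 0.4, rng)
            pi = network_ssd(net, 0.01)
            ab = ssd_after_path(net, 0.01, pi, [(0, 0), (2, 1)])
            # apply in the opposite order by hand
            pi_b = ssd_after_mutation(net, 0.01, pi, (2, 1))
            ba = ssd_after_mutation(net.apply_mutation((2, 1)), 0.01, pi_b, (0, 0))
            np.testing.assert_allclose(ab, ba, atol=1e-10)

    def test_fundamental_matrix_identity(self, rng):
        net = random_network(3, 2, 0.4, rng)
        P = build_tpm(net, 0.05)
        pi = stationary_distribution(P)
        Z = fundamental_matrix(P, pi)
        lhs = Z @ (np.eye(8) - P + np.outer(np.ones(8), pi))
        np.testing.assert_allclose(lhs, np.eye(8), atol=1e-10)
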