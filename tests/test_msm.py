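"""Transition counting, ergodic trimming, reversible maximum-likelihood
estimation, implied timescales and Chapman-Kolmogorov validation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tailmsm import (
    MarkovStateModel,
    MSMResults,
    count_transitions,
    estimate_reversible,
    generate_markov_chain,
    GroundTruthChain,
    implied_timescales,
    largest_connected_set,
    transition_matrix_loglik,
)


class TestCounting:
    def test_hand_counts_lag1(self):
        cm = count_transitions([0, 0, 1, 1, 0], lag=1)
        assert cm.counts.tolist() == [[1, 1], [1, 1]]
        assert cm.total == 4

    def test_hand_counts_lag2(self):
        cm = count_transitions([0, 0, 1, 1, 0], lag=2)
        assert cm.counts.tolist() == [[0, 2], [1, 0]]

    def test_pairs_never_cross_trajectories(self):
        cm = count_transitions([[0, 1], [1, 0]], lag=1)
        assert cm.counts.tolist() == [[0, 1], [1, 0]]

    def test_strided_counts_disjoint_pairs(self):
        cm = count_transitions([0, 1, 0, 1, 0], lag=2, mode="strided")
        # pairs: (x0,x2), (x2,x4) only
        assert cm.counts.tolist() == [[2, 0], [0, 0]]

    def test_lag_longer_than_data_raises(self):
        with pytest.raises(ValueError, match="lag"):
            count_transitions([0, 1, 0], lag=3)


class TestLargestConnectedSet:
    def test_fully_connected(self):
        assert largest_connected_set(np.array([[5, 1], [1, 3]])).tolist() == [0, 1]

    def test_size_tie_broken_by_counts(self):
        assert largest_connected_set(np.array([[5, 0], [0, 3]])).tolist() == [0]

    def test_one_way_edge_excluded(self):
        C = np.array([[1, 2, 0], [2, 1, 1], [0, 0, 1]])  # 2 never returns
        assert largest_connected_set(C).tolist() == [0, 1]

    def test_singleton_warns(self):
        with pytest.warns(UserWarning, match="single state"):
            largest_connected_set(np.array([[0, 1], [0, 1]]))


def _loglik_oracle(C: np.ndarray, n_restarts: int = 3) -> float:
    """Direct constrained maximization of the reversible likelihood over
    symmetric positive auxiliary variables (independent of the fixed-point
    estimator under test)."""
    from scipy.optimize import minimize

    n = C.shape[0]
    iu = np.triu_indices(n)

    def negll(theta):
        X = np.zeros((n, n))
        X[iu] = np.exp(theta)
        X = X + X.T - np.diag(np.diag(X))
        T = X / X.sum(axis=1)[:, None]
        return -transition_matrix_loglik(C, T)

    best = np.inf
    for s in range(n_restarts):
        x0 = np.log((C + C.T)[iu] + 0.5) + 0.01 * np.random.default_rng(s).normal(
            size=iu[0].size)
        res = minimize(negll, x0, method="L-BFGS-B",
                       options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12})
        best = min(best, res.fun)
    return -best


class TestReversibleEstimation:
    def test_symmetric_counts_are_fixed_point(self):
        C = np.array([[90.0, 8, 2], [8, 80, 10], [2, 10, 90]])
        T, pi, _ = estimate_reversible(C)
        assert np.allclose(T, C / C.sum(axis=1)[:, None], atol=1e-12)
        assert np.allclose(pi, np.array([100, 98, 102]) / 300, atol=1e-12)

    def test_two_state_equals_row_normalization(self):
        C = np.array([[12.0, 5], [9, 30]])
        T, _, _ = estimate_reversible(C)
        assert np.allclose(T, C / C.sum(axis=1)[:, None], atol=1e-10)

    def test_nonsymmetric_counts_maximize_reversible_likelihood(self):
        C = np.array([[4.0, 1, 3], [2, 4, 2], [1, 3, 4]])
        T, pi, _ = estimate_reversible(C)
        flux = pi[:, None] * T
        assert np.max(np.abs(flux - flux.T)) < 1e-10
        assert transition_matrix_loglik(C, T) >= _loglik_oracle(C) - 1e-6

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(2, 6), st.integers(0, 10_000))
    def test_detailed_balance_and_stationarity_properties(self, n, seed):
        rng = np.random.default_rng(seed)
        C = rng.integers(1, 50, size=(n, n)).astype(float)
        T, pi, _ = estimate_reversible(C)
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-10)
        flux = pi[:, None] * T
        assert np.max(np.abs(flux - flux.T)) < 1e-8
        assert np.max(np.abs(pi @ T - pi)) < 1e-10
        assert np.all(pi > 0)

    def test_zero_outgoing_row_rejected(self):
        with pytest.raises(ValueError, match="outgoing"):
            estimate_reversible(np.array([[1.0, 1], [0, 0]]))


class TestModelFit:
    def test_entries_within_multinomial_error(self, reversible_chain_4):
        d = generate_markov_chain(reversible_chain_4, 200_000, seed=3)
        res = MarkovStateModel(d, 1).fit()
        T = reversible_chain_4.transition_matrix
        counts = res.count_matrix.counts
        for i in range(4):
            n_i = counts[i].sum()
            for j in range(4):
                se = math.sqrt(max(T[i, j] * (1 - T[i, j]) / n_i, 1e-12))
                assert abs(res.transition_matrix[i, j] - T[i, j]) < 3 * se + 1e-6

    def test_spectrum_structure(self, reversible_chain_4):
        d = generate_markov_chain(reversible_chain_4, 50_000, seed=4)
        res = MarkovStateModel(d, 2).fit()
        assert res.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert np.allclose(res.left_eigenvectors[:, 0], res.stationary, atol=1e-10)

    def test_nonreversible_mode_row_normalizes(self):
        d = [0, 1, 0, 1, 1, 0, 0, 1, 0, 1]
        res = MarkovStateModel(d, 1, reversible=False).fit()
        C = res.count_matrix.counts
        assert np.allclose(res.transition_matrix, C / C.sum(1)[:, None])

    def test_inactive_states_trimmed(self):
        # state 2 appears once at a trajectory end: no return path
        d = [0, 1, 0, 1, 0, 1, 2]
        res = MarkovStateModel(d, 1).fit()
        assert res.active_set.tolist() == [0, 1]
        assert res.active_fraction < 1.0

    def test_from_transition_matrix_roundtrip(self, three_state_linear):
        res = MSMResults.from_transition_matrix(
            three_state_linear.transition_matrix, lagtime=1)
        assert np.allclose(res.stationary, 1 / 3, atol=1e-12)
        assert res.eigenvalues[0] == pytest.approx(1.0)


class TestImpliedTimescales:
    def test_two_state_closed_form_and_flatness(self):
        chain = GroundTruthChain(np.array([[0.85, 0.15], [0.15, 0.85]]))
        d = generate_markov_chain(chain, 300_000, seed=5)
        its = implied_timescales(d, [1, 2, 4], m=1)
        t_true = -1.0 / math.log(0.7)
        ts = its.timescales_ns[:, 0]
        assert np.all(np.abs(ts - t_true) / t_true < 0.05)
        assert np.max(np.abs(ts - ts.mean())) / ts.mean() < 0.10

    def test_negative_eigenvalue_below_resolution_marker(self):
        # deterministic alternation: lambda_2 = -1, no valid timescale
        d = np.tile([0, 1], 2_000)
        its = implied_timescales(d, [1], m=1)
        assert np.isnan(its.timescales_ns[0, 0])

    def test_dataframe_units(self):
        chain = GroundTruthChain(np.array([[0.9, 0.1], [0.1, 0.9]]))
        d = generate_markov_chain(chain, 20_000, seed=6)
        df = implied_timescales(d, [1, 2], m=1, dt_ns=0.5).to_dataframe()
        assert list(df["lag_ns"]) == [0.5, 1.0]


class TestCKTest:
    def _fit(self, dtrajs, lag=1):
        return MarkovStateModel(dtrajs, lag).fit()

    def test_markovian_data_passes(self, reversible_chain_4):
        dtrajs = [generate_markov_chain(reversible_chain_4, 10_000, seed=40 + i)
                  for i in range(10)]
        res = self._fit(dtrajs)
        ck = res.ck_test([[0, 1], [2, 3]], multiples=(2, 3, 4, 5),
                         n_boot=30, seed=0)
        assert ck.passed(z_threshold=3.0)
        for k in ck.multiples:
            assert np.allclose(ck.predicted[k].sum(axis=1), 1.0, atol=1e-8)
            assert np.allclose(ck.estimated[k].sum(axis=1), 1.0, atol=1e-8)

    def test_hidden_state_observable_fails(self):
        # 0 <-> 1 exchanges fast, 2 is a deep trap reached through 1;
        # lumping {1, 2} hides the trap and breaks Markovianity
        T = np.array([[0.80, 0.20, 0.00],
                      [0.20, 0.78, 0.02],
                      [0.00, 0.02, 0.98]])
        chain = GroundTruthChain(T)
        dtrajs = [np.where(generate_markov_chain(chain, 10_000, seed=60 + i) == 2,
                           1, generate_markov_chain(chain, 10_000, seed=60 + i))
                  for i in range(10)]
        res = self._fit(dtrajs)
        ck = res.ck_test([[0], [1]], multiples=(2, 3, 4, 5), n_boot=30, seed=0)
        assert not ck.passed(z_threshold=3.0)

    def test_identity_chain_trivial_agreement(self):
        d = np.zeros(100, dtype=int)
        res = self._fit(d)
        ck = res.ck_test([[0]], multiples=(2, 3), n_boot=5, seed=0)
        for k in ck.multiples:
            assert ck.predicted[k][0, 0] == pytest.approx(1.0)
            assert ck.estimated[k][0, 0] == pytest.approx(1.0)

    def test_insufficient_counts_flagged_not_fatal(self, reversible_chain_4):
        d = generate_markov_chain(reversible_chain_4, 30, seed=1)
        res = self._fit(d)
        sets = [[int(s)] for s in res.active_set]
        with pytest.warns(UserWarning, match="flagged"):
            ck = res.ck_test(sets, multiples=(2, 25), n_boot=5, seed=0)
        assert 25 in ck.flagged and 2 not in ck.flagged

    def test_sets_must_partition_active_set(self, reversible_chain_4):
        d = generate_markov_chain(reversible_chain_4, 5_000, seed=2)
        res = self._fit(d)
        with pytest.raises(ValueError, match="partition"):
            res.ck_test([[0, 1]], multiples=(2,))
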