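"""Generators against their analytic oracles: chain statistics, Gaussian
emissions, Langevin equilibrium properties, toy-tail construction."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from tailmsm import (
    EmissionModel,
    GroundTruthChain,
    PotentialSpec,
    ToyTailSpec,
    emit_features,
    generate_langevin,
    generate_markov_chain,
    generate_toy_tail,
    oracle_kinetics,
)


class TestGroundTruthChain:
    def test_rejects_non_stochastic_rows_naming_offender(self):
        with pytest.raises(ValueError, match="rows \\[1\\]"):
            GroundTruthChain(np.array([[0.5, 0.5], [0.5, 0.6]]))

    def test_rejects_negative_entries(self):
        with pytest.raises(ValueError, match="negative"):
            GroundTruthChain(np.array([[1.2, -0.2], [0.5, 0.5]]))

    def test_stationary_solves_balance(self, two_state_chain):
        pi = two_state_chain.stationary
        assert np.allclose(pi @ two_state_chain.transition_matrix, pi, atol=1e-12)
        assert np.allclose(pi, [2 / 3, 1 / 3])


class TestGenerateMarkovChain:
    def test_absorbing_identity_stays_put(self):
        chain = GroundTruthChain(np.eye(2))
        traj = generate_markov_chain(chain, 5, seed=0, start=0)
        assert traj.tolist() == [0, 0, 0, 0, 0]

    def test_deterministic_alternation(self):
        chain = GroundTruthChain(np.array([[0.0, 1.0], [1.0, 0.0]]))
        traj = generate_markov_chain(chain, 4, seed=0, start=0)
        assert traj.tolist() == [0, 1, 0, 1]

    def test_empirical_transition_frequencies_converge(self, two_state_chain):
        n = 200_000
        traj = generate_markov_chain(two_state_chain, n, seed=42)
        T = two_state_chain.transition_matrix
        for i in range(2):
            visits = np.where(traj[:-1] == i)[0]
            for j in range(2):
                frac = np.mean(traj[visits + 1] == j)
                se = math.sqrt(T[i, j] * (1 - T[i, j]) / visits.size)
                assert abs(frac - T[i, j]) < 3 * se

    def test_bit_reproducible(self, two_state_chain):
        a = generate_markov_chain(two_state_chain, 1000, seed=7)
        b = generate_markov_chain(two_state_chain, 1000, seed=7)
        assert np.array_equal(a, b)

    def test_too_short_raises(self, two_state_chain):
        with pytest.raises(ValueError, match="n_steps"):
            generate_markov_chain(two_state_chain, 1)


class TestEmitFeatures:
    def test_noiseless_limit_reproduces_means(self):
        em = EmissionModel(means=[[1.0, 2.0], [-3.0, 4.0]],
                           covariances=np.zeros((2, 2, 2)))
        states = np.array([0, 1, 1, 0])
        X = emit_features(states, em, seed=0)
        assert np.array_equal(X, em.means[states])

    def test_per_state_sample_means(self):
        em = EmissionModel(means=[[-1.0], [1.0]],
                           covariances=np.full((2, 1, 1), 0.01))
        states = np.tile([0, 1], 50_000)
        X = emit_features(states, em, seed=3)
        for s, mu in [(0, -1.0), (1, 1.0)]:
            assert abs(X[states == s, 0].mean() - mu) < 0.01

    def test_angle_pairs_clipped_to_unit_disk(self):
        em = EmissionModel(means=[[0.9, 0.9]],
                           covariances=np.full((1, 2, 2), 0.0) + 0.09 * np.eye(2),
                           feature_kinds=("angle", "angle"))
        X = emit_features(np.zeros(10_000, dtype=int), em, seed=1)
        assert np.all(np.hypot(X[:, 0], X[:, 1]) <= 1 + 1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="incompatible"):
            EmissionModel(means=[[0.0, 1.0]], covariances=np.eye(3)[None])

    def test_asymmetric_covariance_raises(self):
        cov = np.array([[[1.0, 0.5], [0.2, 1.0]]])
        with pytest.raises(ValueError, match="not symmetric"):
            EmissionModel(means=[[0.0, 0.0]], covariances=cov)


class TestLangevin:
    def test_no_force_no_noise_is_constant(self):
        spec = PotentialSpec(dimension=1, centers=[[0.0], [50.0]],
                             depths=[1.0, 1.0], widths=[1.0, 1.0],
                             kT=0.0, dt=0.01, n_steps=100, seed=0)
        x = generate_langevin(spec)
        assert np.allclose(x, x[0])

    def test_equipartition_in_harmonic_region(self):
        # kT well below depth: the Gaussian well bottom is locally harmonic
        # with k = depth / width^2; exact variance from Boltzmann quadrature
        spec = PotentialSpec(dimension=1, centers=[[0.0], [60.0]],
                             depths=[8.0, 0.5], widths=[1.0, 1.0],
                             kT=0.1, dt=0.004, n_steps=300_000, seed=3)
        x = generate_langevin(spec)[:, 0]
        Z = quad(lambda z: math.exp(8 * math.exp(-z**2 / 2) / 0.1), -3, 3)[0]
        v_exact = quad(lambda z: z * z * math.exp(8 * math.exp(-z**2 / 2) / 0.1),
                       -3, 3)[0] / Z
        assert abs(x.var() - v_exact) / v_exact < 0.05

    def test_symmetric_double_well_splits_evenly(self):
        spec = PotentialSpec(dimension=1, centers=[[-0.8], [0.8]],
                             depths=[1.5, 1.5], widths=[0.7, 0.7],
                             kT=1.0, dt=0.005, n_steps=400_000, seed=11)
        x = generate_langevin(spec)[:, 0]
        assert abs((x < 0).mean() - 0.5) < 0.01

    def test_step_size_validation(self):
        with pytest.raises(ValueError, match="reduce dt"):
            PotentialSpec(dimension=1, centers=[[0.0], [5.0]],
                          depths=[1.0, 1.0], widths=[0.1, 0.1],
                          kT=1.0, dt=0.01, n_steps=10, seed=0)

    def test_reproducible(self):
        spec = PotentialSpec(dimension=2, centers=[[-1.0, 0], [1.0, 0]],
                             depths=[2.0, 2.0], widths=[0.6, 0.6],
                             kT=1.0, dt=0.005, n_steps=500, seed=5)
        assert np.array_equal(generate_langevin(spec), generate_langevin(spec))


class TestToyTail:
    def _spec(self, n_states=1, kappa=1e12, n_res=8):
        T = np.eye(n_states) if n_states == 1 else None
        if T is None:
            raise NotImplementedError
        chain = GroundTruthChain(T)
        return ToyTailSpec(n_residues=n_res,
                           torsion_means=np.full(n_states, -1.0),
                           torsion_concentrations=np.full(n_states, kappa),
                           chain=chain)

    def test_infinite_concentration_freezes_conformation(self):
        coords, states = generate_toy_tail(self._spec(), 50, seed=0)
        assert np.allclose(coords, coords[0], atol=1e-4)

    def test_bond_lengths_exact(self):
        spec = self._spec(kappa=2.0)
        coords, _ = generate_toy_tail(spec, 100, seed=1)
        d = np.linalg.norm(np.diff(coords, axis=1), axis=2)
        assert np.allclose(d, 3.8, atol=1e-9)

    def test_invalid_concentration_raises(self):
        chain = GroundTruthChain(np.eye(2))
        with pytest.raises(ValueError, match="concentration"):
            ToyTailSpec(n_residues=6, torsion_means=np.zeros(2),
                        torsion_concentrations=np.array([1.0, 0.0]),
                        chain=chain)

    def test_hidden_states_returned_and_reproducible(self, reversible_chain_4):
        spec = ToyTailSpec(n_residues=6,
                           torsion_means=np.array([-2.0, -0.5, 0.5, 2.0]),
                           torsion_concentrations=np.full(4, 20.0),
                           chain=reversible_chain_4)
        c1, s1 = generate_toy_tail(spec, 500, seed=9)
        c2, s2 = generate_toy_tail(spec, 500, seed=9)
        assert np.array_equal(c1, c2) and np.array_equal(s1, s2)
        assert s1.shape == (500,) and set(np.unique(s1)) <= {0, 1, 2, 3}


class TestOracleKinetics:
    def test_two_state_geometric_waiting_time(self, two_state_chain):
        ok = oracle_kinetics(two_state_chain, [0], [1])
        assert abs(ok.mfpt_ns - 10.0) < 1e-10

    def test_two_state_timescale(self, two_state_chain):
        ok = oracle_kinetics(two_state_chain, [0], [1])
        assert abs(ok.implied_timescales_ns[0] - (-1 / math.log(0.7))) < 1e-10

    def test_three_state_linear_solve(self):
        chain = GroundTruthChain(np.array(
            [[0.9, 0.1, 0.0], [0.1, 0.8, 0.1], [0.0, 0.1, 0.9]]))
        assert abs(oracle_kinetics(chain, [0], [2]).mfpt_ns - 30.0) < 1e-9

    def test_unreachable_sink_flagged_infinite(self):
        chain = GroundTruthChain(np.array(
            [[0.5, 0.5, 0.0], [0.5, 0.5, 0.0], [0.0, 0.5, 0.5]]))
        with pytest.warns(UserWarning, match="unreachable"):
            ok = oracle_kinetics(chain, [0], [2])
        assert math.isinf(ok.mfpt_ns) and not ok.reachable

    def test_overlapping_sets_raise(self, two_state_chain):
        with pytest.raises(ValueError, match="disjoint"):
            oracle_kinetics(two_state_chain, [0], [0, 1])

    def test_mfpt_matches_brute_force_passages(self, two_state_chain):
        # independent oracle: simulate first-passage events directly
        rng = np.random.default_rng(123)
        T = two_state_chain.transition_matrix
        cum = np.cumsum(T, axis=1)
        times = np.empty(10_000)
        for i in range(times.size):
            s, t = 0, 0
            while s != 1:
                s = int(np.searchsorted(cum[s], rng.random(), side="right"))
                t += 1
            times[i] = t
        se = times.std(ddof=1) / math.sqrt(times.size)
        assert abs(times.mean() - oracle_kinetics(two_state_chain, [0], [1]).mfpt_ns) < 3 * se
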