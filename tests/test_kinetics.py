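"""MFPT linear solves, committor boundary-value problems, TPT flux
identities, pathway decomposition against exhaustive enumeration, and
kinetic-network export."""

import itertools

import numpy as np
import pytest

from tailmsm import (
    FluxNetwork,
    MSMResults,
    MarkovStateModel,
    coarse_grained_kinetics,
    committors,
    decompose_pathways,
    export_network,
    generate_markov_chain,
    import_network,
    mfpt,
    pcca,
    tpt_flux,
)


@pytest.fixture
def linear3(three_state_linear):
    return MSMResults.from_transition_matrix(
        three_state_linear.transition_matrix, lagtime=1)


@pytest.fixture
def random_reversible5():
    rng = np.random.default_rng(12)
    S = rng.integers(1, 40, size=(5, 5)).astype(float)
    S = S + S.T
    T = S / S.sum(axis=1)[:, None]
    pi = S.sum(axis=1) / S.sum()
    return MSMResults.from_transition_matrix(T, pi=pi)


class TestMFPT:
    def test_two_state_with_lag_units(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        res = MSMResults.from_transition_matrix(T, lagtime=1, dt_ns=5.0)
        assert mfpt(res, [0], [1]) == pytest.approx(50.0)  # 10 steps x 5 ns

    def test_immediate_absorption_is_one_lag(self):
        T = np.array([[0.0, 1.0], [0.5, 0.5]])
        res = MSMResults.from_transition_matrix(
            T, pi=np.array([1 / 3, 2 / 3]))
        assert mfpt(res, [0], [1]) == pytest.approx(res.lag_ns)

    def test_three_state_linear_solve(self, linear3):
        assert mfpt(linear3, [0], [2]) == pytest.approx(30.0)

    def test_disjointness_enforced(self, linear3):
        with pytest.raises(ValueError, match="disjoint"):
            mfpt(linear3, [0, 1], [1, 2])


class TestCommittors:
    def test_boundary_only_two_state(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        res = MSMResults.from_transition_matrix(T)
        qp, qm = committors(res, [0], [1])
        assert np.allclose(qp, [0.0, 1.0])
        assert np.allclose(qm, [1.0, 0.0])

    def test_symmetric_middle_state_half(self, linear3):
        qp, _ = committors(linear3, [0], [2])
        assert qp[1] == pytest.approx(0.5, abs=1e-12)

    def test_reversible_identity(self, random_reversible5):
        qp, qm = committors(random_reversible5, [0], [4])
        assert np.max(np.abs(qm - (1 - qp))) < 1e-10

    def test_bounded(self, random_reversible5):
        qp, qm = committors(random_reversible5, [0, 1], [4])
        assert np.all((qp >= -1e-12) & (qp <= 1 + 1e-12))
        assert np.all((qm >= -1e-12) & (qm <= 1 + 1e-12))


class TestTPTFlux:
    def test_linear_chain_closed_form(self, linear3):
        # f_01 = pi_0 * q-_0 * T_01 * q+_1 = (1/3)(1)(0.1)(0.5) = 1/60
        fl = tpt_flux(linear3, [0], [2])
        assert fl.gross_flux[0, 1] == pytest.approx(1 / 60)
        assert fl.total_flux == pytest.approx(1 / 60)

    def test_identity_matrix_zero_flux(self):
        res = MSMResults.from_transition_matrix(np.eye(2),
                                                pi=np.array([0.5, 0.5]))
        fl = tpt_flux(res, [0], [1])
        assert fl.total_flux == 0.0
        assert np.all(fl.gross_flux == 0)

    def test_net_flux_conservation_at_intermediates(self, random_reversible5):
        fl = tpt_flux(random_reversible5, [0], [4])
        inflow = fl.net_flux.sum(axis=0)
        outflow = fl.net_flux.sum(axis=1)
        for i in (1, 2, 3):
            assert abs(inflow[i] - outflow[i]) < 1e-10

    def test_forward_backward_symmetry_of_total_flux(self, random_reversible5):
        f_ab = tpt_flux(random_reversible5, [0, 1], [4]).total_flux
        f_ba = tpt_flux(random_reversible5, [4], [0, 1]).total_flux
        assert abs(f_ab - f_ba) < 1e-10

    def test_flux_in_per_ns_units(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        r1 = MSMResults.from_transition_matrix(T, dt_ns=1.0)
        r5 = MSMResults.from_transition_matrix(T, dt_ns=5.0)
        assert tpt_flux(r1, [0], [1]).total_flux == pytest.approx(
            5 * tpt_flux(r5, [0], [1]).total_flux)


def _manual_flux(net: np.ndarray, A, B, total=None) -> FluxNetwork:
    n = net.shape[0]
    return FluxNetwork(A=np.asarray(A), B=np.asarray(B),
                       q_plus=np.zeros(n), q_minus=np.zeros(n),
                       gross_flux=net.copy(), net_flux=net.copy(),
                       total_flux=total if total is not None
                       else float(net[A].sum()), lag_ns=1.0)


def _enumeration_decomposition(net, A, B, max_paths=100):
    """Oracle: exhaustive simple-path search for the max-bottleneck path at
    every subtraction step (independent of the Dijkstra-style search)."""
    cap = net.copy()
    n = cap.shape[0]
    nodes = range(n)
    total = float(net[list(A)].sum())
    out = []
    for _ in range(max_paths):
        best_path, best_b = None, 0.0
        for a in A:
            for b in B:
                inner = [v for v in nodes if v not in set(A) | set(B)]
                for r in range(len(inner) + 1):
                    for mid in itertools.permutations(inner, r):
                        path = (a, *mid, b)
                        bott = min(cap[u, v] for u, v in zip(path, path[1:]))
                        if bott > best_b:
                            best_b, best_path = bott, path
        if best_path is None or best_b <= 1e-12 * total:
            break
        for u, v in zip(best_path, best_path[1:]):
            cap[u, v] -= best_b
        out.append((best_path, 100.0 * best_b / total))
    return out


class TestPathwayDecomposition:
    def test_single_route_is_100_percent(self, linear3):
        fl = decompose_pathways(tpt_flux(linear3, [0], [2]))
        assert fl.pathways == [((0, 1, 2), pytest.approx(100.0))]

    def test_parallel_routes_share_by_flux(self):
        # A=0, B=3; routes 0->1->3 (3e) and 0->2->3 (e)
        e = 1e-4
        net = np.zeros((4, 4))
        net[0, 1] = net[1, 3] = 3 * e
        net[0, 2] = net[2, 3] = e
        fl = decompose_pathways(_manual_flux(net, [0], [3], total=4 * e))
        shares = {p: s for p, s in fl.pathways}
        assert shares[(0, 1, 3)] == pytest.approx(75.0)
        assert shares[(0, 2, 3)] == pytest.approx(25.0)

    def test_full_decomposition_matches_enumeration_oracle(
            self, random_reversible5):
        fl = tpt_flux(random_reversible5, [0], [4])
        fl = decompose_pathways(fl)
        oracle = _enumeration_decomposition(fl.net_flux, [0], [4])
        assert len(fl.pathways) == len(oracle)
        for (p1, s1), (p2, s2) in zip(fl.pathways, oracle):
            assert p1 == p2
            assert s1 == pytest.approx(s2, abs=1e-9)
        assert sum(s for _, s in fl.pathways) == pytest.approx(100.0, abs=1e-6)

    def test_decomposed_fluxes_sum_to_total(self, random_reversible5):
        fl = decompose_pathways(tpt_flux(random_reversible5, [0], [4]))
        recon = sum(s / 100.0 * fl.total_flux for _, s in fl.pathways)
        assert recon == pytest.approx(fl.total_flux, rel=1e-9)

    def test_max_paths_truncation(self, random_reversible5):
        fl = decompose_pathways(tpt_flux(random_reversible5, [0], [4]),
                                max_paths=1)
        assert len(fl.pathways) == 1


class TestCoarseGrainedKinetics:
    def _summary(self, chain, n=120_000, m=2, seed=9):
        d = generate_markov_chain(chain, n, seed=seed)
        res = MarkovStateModel(d, 1).fit()
        cg = pcca(res, m)
        return coarse_grained_kinetics(res, cg, source=0, sink=m - 1)

    def test_two_macrostates_reciprocal_rates(self, reversible_chain_4):
        s = self._summary(reversible_chain_4, m=2)
        off = s.mfpt_ns[~np.eye(2, dtype=bool)]
        assert off.size == 2 and np.all(off > 0)
        assert s.rates_per_ns[0, 1] == pytest.approx(1 / s.mfpt_ns[0, 1])
        assert s.populations_pct.sum() == pytest.approx(100.0, abs=0.1)

    def test_summary_text_contains_major_path(self, reversible_chain_4):
        s = self._summary(reversible_chain_4, m=2)
        path, share = s.major_pathway()
        assert "->" in path and 0 < share <= 100 + 1e-6
        assert "Macrostate kinetics" in s.summary()


class TestNetworkExport:
    def test_round_trip_preserves_attributes(self, tmp_path, reversible_chain_4):
        d = generate_markov_chain(reversible_chain_4, 100_000, seed=3)
        res = MarkovStateModel(d, 1).fit()
        cg = pcca(res, 2)
        summary = coarse_grained_kinetics(res, cg)
        G = export_network(summary, dot_path=tmp_path / "net.dot",
                           json_path=tmp_path / "net.json")
        H = import_network(tmp_path / "net.json")
        assert set(G.nodes) == set(H.nodes) and set(G.edges) == set(H.edges)
        for n in G.nodes:
            assert G.nodes[n]["population_pct"] == H.nodes[n]["population_pct"]
        for e in G.edges:
            assert G.edges[e]["mfpt_ns"] == H.edges[e]["mfpt_ns"]
        assert (tmp_path / "net.dot").read_text().startswith("digraph")

    def test_edge_weight_ordering_matches_inverse_mfpt(self, reversible_chain_4):
        d = generate_markov_chain(reversible_chain_4, 100_000, seed=4)
        res = MarkovStateModel(d, 1).fit()
        summary = coarse_grained_kinetics(res, pcca(res, 3))
        G = export_network(summary)
        edges = list(G.edges(data=True))
        by_rate = sorted(edges, key=lambda e: -e[2]["rate_per_ns"])
        by_width = sorted(edges, key=lambda e: -e[2]["penwidth"])
        assert [e[:2] for e in by_rate] == [e[:2] for e in by_width]
        by_mfpt = sorted(edges, key=lambda e: e[2]["mfpt_ns"])
        assert [e[:2] for e in by_mfpt] == [e[:2] for e in by_rate]
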