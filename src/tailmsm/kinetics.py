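"""Equilibrium kinetics from a fitted MSM: MFPTs, committors, transition
path theory fluxes, dominant pathways, and kinetic-network export.

Mean first passage times come from the absorbing-chain linear system; the
inverse MFPT is the kinetic rate.  Transition path theory decomposes the
equilibrium A->B flux through committor functions into gross fluxes
f_ij = pi_i q-_i T_ij q+_j and net fluxes f+_ij = max(0, f_ij - f_ji), and
the dominant pathways are extracted by strongest-bottleneck-first
subtraction on the net-flux graph.  All reported times are in ns.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field

import numpy as np

from .msm import MSMResults
from .coarse_grain import CoarseGrainedModel


def _check_sets(n: int, A, B):
    A = np.asarray(sorted(set(int(a) for a in A)), dtype=np.int64)
    B = np.asarray(sorted(set(int(b) for b in B)), dtype=np.int64)
    if A.size == 0 or B.size == 0:
        raise ValueError("A and B must be nonempty")
    if np.intersect1d(A, B).size:
        raise ValueError("A and B must be disjoint")
    if A.max() >= n or B.max() >= n or A.min() < 0 or B.min() < 0:
        raise ValueError("A/B indices outside the active set")
    return A, B


def mfpt(msm: MSMResults, A, B) -> float:
    """Mean first passage time A -> B in ns (pi-weighted over A).

    Solves (I - T_C) m_C = 1 on C = complement(B); each step of T spans the
    model lag, so the result is steps * lag_ns.
    """
    T = msm.transition_matrix
    n = T.shape[0]
    A, B = _check_sets(n, A, B)
    C = np.setdiff1d(np.arange(n), B)
    m = np.zeros(n)
    m[C] = np.linalg.solve(np.eye(C.size) - T[np.ix_(C, C)], np.ones(C.size))
    w = msm.stationary[A] / msm.stationary[A].sum()
    return float(w @ m[A]) * msm.lag_ns


def committors(msm: MSMResults, A, B) -> tuple[np.ndarray, np.ndarray]:
    """Forward and backward committors (q+, q-) for source A and sink B.

    q+ solves the discrete boundary-value problem (0 on A, 1 on B, harmonic
    in between); q- is the committor of the time-reversed chain, which for
    a reversible model equals 1 - q+.
    """
    T = msm.transition_matrix
    pi = msm.stationary
    n = T.shape[0]
    A, B = _check_sets(n, A, B)
    inter = np.setdiff1d(np.arange(n), np.concatenate([A, B]))

    def solve(Tm, source, sink):
        q = np.zeros(n)
        q[sink] = 1.0
        if inter.size:
            M = np.eye(inter.size) - Tm[np.ix_(inter, inter)]
            rhs = Tm[np.ix_(inter, sink)].sum(axis=1)
            try:
                q[inter] = np.linalg.solve(M, rhs)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    f"intermediate states {inter.tolist()} are disconnected "
                    "from the boundary sets"
                ) from exc
        return q

    q_plus = solve(T, A, B)
    Trev = (pi[:, None] * T).T / pi[:, None]  # time-reversed chain
    q_minus = solve(Trev, B, A)
    return q_plus, q_minus


@dataclass
class FluxNetwork:
    """Transition-path-theory flux decomposition for one (A, B) pair.

    Fluxes are per ns (probability flux per unit time); ``pathways`` holds
    (state sequence, flux share in %) in extraction order, strongest first.
    """

    A: np.ndarray
    B: np.ndarray
    q_plus: np.ndarray
    q_minus: np.ndarray
    gross_flux: np.ndarray
    net_flux: np.ndarray
    total_flux: float                # A -> B, per ns
    lag_ns: float
    pathways: list[tuple[tuple[int, ...], float]] = field(default_factory=list)


def tpt_flux(msm: MSMResults, A, B,
             q_plus: np.ndarray | None = None,
             q_minus: np.ndarray | None = None) -> FluxNetwork:
    """Gross and net reactive fluxes from A to B, in events per ns."""
    T = msm.transition_matrix
    pi = msm.stationary
    n = T.shape[0]
    A, B = _check_sets(n, A, B)
    if q_plus is None or q_minus is None:
        q_plus, q_minus = committors(msm, A, B)
    f = pi[:, None] * q_minus[:, None] * T * q_plus[None, :]
    np.fill_diagonal(f, 0.0)
    f /= msm.lag_ns  # per step -> per ns
    fnet = np.clip(f - f.T, 0.0, None)
    notA = np.setdiff1d(np.arange(n), A)
    total = float(fnet[np.ix_(A, notA)].sum())
    return FluxNetwork(A=A, B=B, q_plus=q_plus, q_minus=q_minus,
                       gross_flux=f, net_flux=fnet, total_flux=total,
                       lag_ns=msm.lag_ns)


def _widest_path(cap: np.ndarray, A: np.ndarray, B: np.ndarray):
    """Max-bottleneck path from any state in A to any state in B.

    Dijkstra variant maximizing the minimum edge capacity; returns
    (path tuple, bottleneck) or (None, 0).
    """
    n = cap.shape[0]
    best = np.zeros(n)
    prev = np.full(n, -1)
    heap = []
    for a in A:
        best[a] = np.inf
        heapq.heappush(heap, (-np.inf, int(a)))
    visited = np.zeros(n, dtype=bool)
    Bset = set(int(b) for b in B)
    while heap:
        negw, u = heapq.heappop(heap)
        if visited[u]:
            continue
        visited[u] = True
        if u in Bset:
            path = [u]
            while prev[path[-1]] != -1:
                path.append(int(prev[path[-1]]))
            return tuple(reversed(path)), float(best[u])
        for v in np.nonzero(cap[u] > 0)[0]:
            w = min(best[u], cap[u, v])
            if w > best[v]:
                best[v] = w
                prev[v] = u
                heapq.heappush(heap, (-w, int(v)))
    return None, 0.0


def coarse_grain_flux(flux: FluxNetwork, sets: list[np.ndarray],
                      source: int, sink: int) -> FluxNetwork:
    """Aggregate a microstate flux network onto disjoint state sets.

    Gross fluxes add over set pairs; the coarse net flux is the positive
    part of the gross-flux antisymmetry, and the total A->B flux is
    conserved.  Committors are averaged per set (unweighted mean; used for
    reporting only).
    """
    m = len(sets)
    F = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            if a == b:
                continue
            F[a, b] = flux.gross_flux[np.ix_(sets[a], sets[b])].sum()
    Fnet = np.clip(F - F.T, 0.0, None)
    A = np.asarray([source])
    B = np.asarray([sink])
    notA = np.setdiff1d(np.arange(m), A)
    total = float(Fnet[np.ix_(A, notA)].sum())
    qp = np.asarray([flux.q_plus[s].mean() for s in sets])
    qm = np.asarray([flux.q_minus[s].mean() for s in sets])
    return FluxNetwork(A=A, B=B, q_plus=qp, q_minus=qm, gross_flux=F,
                       net_flux=Fnet, total_flux=total, lag_ns=flux.lag_ns)


def decompose_pathways(flux: FluxNetwork, max_paths: int | None = None,
                       min_fraction: float = 1e-12) -> FluxNetwork:
    """Strongest-bottleneck-first pathway decomposition of the net flux.

    Repeatedly extracts the max-bottleneck path from A to B on the net-flux
    graph, subtracts its bottleneck flux along the path, and records the
    path with its share of the total A->B flux (%).  Stops when the flux is
    numerically exhausted (below ``min_fraction`` of the total) or
    ``max_paths`` pathways have been extracted.  The decomposition order is
    part of the definition: shares depend on subtracting strongest first.
    """
    cap = flux.net_flux.copy()
    total = flux.total_flux
    paths: list[tuple[tuple[int, ...], float]] = []
    if total <= 0:
        flux.pathways = paths
        return flux
    while max_paths is None or len(paths) < max_paths:
        path, bottleneck = _widest_path(cap, flux.A, flux.B)
        if path is None or bottleneck <= min_fraction * total:
            break
        for u, v in zip(path[:-1], path[1:]):
            cap[u, v] -= bottleneck
        paths.append((path, 100.0 * bottleneck / total))
    flux.pathways = paths
    return flux


# --------------------------------------------------------------------------
# coarse-grained kinetics summary
# --------------------------------------------------------------------------

@dataclass
class KineticsSummary:
    """Macrostate-level kinetics: populations, pairwise MFPTs, rates, and
    the dominant source->sink pathway (the table-row view of one system)."""

    populations_pct: np.ndarray      # (m,), sums to 100
    mfpt_ns: np.ndarray              # (m, m), diagonal 0
    rates_per_ns: np.ndarray         # elementwise inverse of off-diagonal MFPT
    source: int
    sink: int
    pathways: list[tuple[tuple[int, ...], float]]   # macrostate sequences, share %
    excluded: list[int] = field(default_factory=list)

    @property
    def m(self) -> int:
        return self.populations_pct.size

    @property
    def mfpt_low_ns(self) -> float:
        off = self.mfpt_ns[~np.eye(self.m, dtype=bool)]
        return float(np.min(off[np.isfinite(off)]))

    @property
    def mfpt_high_ns(self) -> float:
        off = self.mfpt_ns[~np.eye(self.m, dtype=bool)]
        return float(np.max(off[np.isfinite(off)]))

    @property
    def highest_population_state(self) -> int:
        return int(np.argmax(self.populations_pct))

    def major_pathway(self) -> tuple[str, float]:
        """Dominant source->sink pathway as '1 -> 3 -> 4' (1-based) + share %."""
        if not self.pathways:
            return "", 0.0
        path, share = self.pathways[0]
        return " -> ".join(str(s + 1) for s in path), share

    def summary(self) -> str:
        path, share = self.major_pathway()
        lines = [
            f"Macrostate kinetics ({self.m} states)",
            "  populations (%): "
            + ", ".join(f"{p:.1f}" for p in self.populations_pct),
            f"  highest-population state: {self.highest_population_state + 1} "
            f"({self.populations_pct.max():.1f}%)",
            f"  MFPT range (ns): {self.mfpt_low_ns:.4g} - {self.mfpt_high_ns:.4g}",
            f"  major transition path {self.source + 1} -> {self.sink + 1}: "
            f"{path} ({share:.1f}%)",
        ]
        return "\n".join(lines)


def coarse_grained_kinetics(msm: MSMResults, cg: CoarseGrainedModel,
                            source: int = 0, sink: int | None = None,
                            max_paths: int = 10) -> KineticsSummary:
    """Macrostate populations, pairwise MFPTs/rates, and dominant pathways.

    MFPTs are computed between crisp macrostate sets on the microstate
    transition matrix (pi-weighted over the source set).  The dominant
    pathway runs from ``source`` to ``sink`` (defaults: first and last
    macrostate): the microstate TPT flux is coarse-grained onto the crisp
    macrostate sets and decomposed strongest-bottleneck-first there.
    """
    sets = cg.macrostate_sets(global_ids=False)
    m = cg.m
    sink = m - 1 if sink is None else sink
    excluded = [j for j in range(m) if cg.populations[j] <= 0]
    if excluded:
        import warnings
        warnings.warn(f"macrostates {excluded} have zero population; excluded")
    M = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            if a == b or a in excluded or b in excluded:
                continue
            M[a, b] = mfpt(msm, sets[a], sets[b])
    with np.errstate(divide="ignore"):
        rates = np.where(M > 0, 1.0 / np.where(M > 0, M, 1.0), 0.0)
    micro_flux = tpt_flux(msm, sets[source], sets[sink])
    macro_flux = coarse_grain_flux(micro_flux, sets, source, sink)
    macro_flux = decompose_pathways(macro_flux, max_paths=max_paths)
    pathways = macro_flux.pathways
    return KineticsSummary(
        populations_pct=100.0 * cg.populations,
        mfpt_ns=M, rates_per_ns=rates, source=source, sink=sink,
        pathways=pathways, excluded=excluded,
    )


# --------------------------------------------------------------------------
# network export
# --------------------------------------------------------------------------

def export_network(summary: KineticsSummary, dot_path=None, json_path=None):
    """Kinetic network with population-weighted nodes and rate-weighted edges.

    Nodes carry the stationary population (%); directed edges carry the
    MFPT (ns) and a drawing weight proportional to the rate (inverse MFPT),
    so the thickest arrows are the fastest transitions.  Returns a networkx
    DiGraph and optionally writes DOT and JSON node/edge lists.
    """
    import networkx as nx

    G = nx.DiGraph()
    m = summary.m
    for j in range(m):
        G.add_node(j, label=f"S{j + 1}",
                   population_pct=round(float(summary.populations_pct[j]), 6))
    finite_rates = summary.rates_per_ns[summary.rates_per_ns > 0]
    rmax = finite_rates.max() if finite_rates.size else 1.0
    for a in range(m):
        for b in range(m):
            if a == b or summary.mfpt_ns[a, b] <= 0:
                continue
            rate = float(summary.rates_per_ns[a, b])
            G.add_edge(a, b, mfpt_ns=round(float(summary.mfpt_ns[a, b]), 9),
                       rate_per_ns=round(rate, 12),
                       penwidth=round(0.5 + 4.5 * rate / rmax, 6))
    if dot_path is not None:
        lines = ["digraph kinetics {"]
        for j, data in G.nodes(data=True):
            size = 0.5 + 1.5 * data["population_pct"] / 100.0
            lines.append(
                f'  {j} [label="{data["label"]}\\n{data["population_pct"]:.1f}%",'
                f' width={size:.3f}];'
            )
        for u, v, data in G.edges(data=True):
            lines.append(
                f'  {u} -> {v} [label="{data["mfpt_ns"]:.3g} ns",'
                f' penwidth={data["penwidth"]:.3f}];'
            )
        lines.append("}")
        with open(dot_path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    if json_path is not None:
        payload = {
            "nodes": [{"id": j, **data} for j, data in G.nodes(data=True)],
            "edges": [{"source": u, "target": v, **data}
                      for u, v, data in G.edges(data=True)],
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1)
    return G


def import_network(json_path):
    """Re-load a kinetic network written by :func:`export_network`."""
    import networkx as nx

    with open(json_path) as fh:
        payload = json.load(fh)
    G = nx.DiGraph()
    for node in payload["nodes"]:
        node = dict(node)
        G.add_node(node.pop("id"), **node)
    for edge in payload["edges"]:
        edge = dict(edge)
        G.add_edge(edge.pop("source"), edge.pop("target"), **edge)
    return G
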