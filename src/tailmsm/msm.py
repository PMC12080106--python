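"""Markov state model estimation and validation.

The estimator follows the fit/results convention:
``MarkovStateModel(dtrajs, lagtime).fit()`` counts transitions at the lag,
trims to the largest strongly connected (ergodic) set, and fits the
maximum-likelihood transition matrix under the detailed-balance constraint
via the standard fixed-point iteration on symmetric auxiliary variables.
The returned :class:`MSMResults` carries the transition matrix, stationary
distribution, full spectrum, and validation/kinetics methods (implied
timescales, Chapman-Kolmogorov test, MFPT, committors, PCCA+).

Reversible estimation is the default because the downstream equilibrium
kinetics (MFPT, transition path theory) presuppose detailed balance; plain
row-normalization is available for diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .synthetic import stationary_distribution


# --------------------------------------------------------------------------
# counting and connectivity
# --------------------------------------------------------------------------

def _as_dtraj_list(dtrajs) -> list[np.ndarray]:
    """Normalize input to a list of 1D integer arrays (a flat sequence of
    ints counts as a single trajectory)."""
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        return [dtrajs.astype(np.int64)]
    if isinstance(dtrajs, (list, tuple)):
        if len(dtrajs) and np.isscalar(dtrajs[0]):
            return [np.asarray(dtrajs, dtype=np.int64)]
        return [np.asarray(d, dtype=np.int64) for d in dtrajs]
    return [np.asarray(dtrajs, dtype=np.int64)]


@dataclass
class CountMatrix:
    """Transition counts at one lag."""

    lag: int
    counts: np.ndarray
    mode: str = "sliding"

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]


def count_transitions(dtrajs, lag: int, mode: str = "sliding",
                      n_states: int | None = None) -> CountMatrix:
    """Count transition pairs (x_t, x_{t+lag}); pairs never cross trajectories.

    ``sliding`` counts every t; ``strided`` counts t = 0, lag, 2*lag, ...
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if mode not in ("sliding", "strided"):
        raise ValueError("mode must be 'sliding' or 'strided'")
    dtrajs = _as_dtraj_list(dtrajs)
    if all(d.size <= lag for d in dtrajs):
        raise ValueError(f"lag {lag} is not shorter than any trajectory")
    if n_states is None:
        n_states = int(max(d.max() for d in dtrajs)) + 1
    C = np.zeros((n_states, n_states))
    for d in dtrajs:
        if d.size <= lag:
            continue
        i = d[:-lag] if mode == "sliding" else d[:-lag:lag]
        j = d[lag:] if mode == "sliding" else d[lag::lag][: i.size]
        np.add.at(C, (i, j), 1)
    return CountMatrix(lag=lag, counts=C, mode=mode)


def largest_connected_set(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """States of the largest strongly connected component of the count graph.

    Components are compared by size; equal-sized components are broken by
    larger total counts.  A singleton result is allowed (with a warning).
    """
    C = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    adj = sparse.csr_matrix(C > 0)
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    best, best_key = None, None
    for c in range(n_comp):
        members = np.where(labels == c)[0]
        key = (members.size, C[np.ix_(members, members)].sum())
        if best_key is None or key > best_key:
            best, best_key = members, key
    if best.size == 1:
        warnings.warn("largest connected set is a single state")
    return best


# --------------------------------------------------------------------------
# reversible maximum-likelihood estimation
# --------------------------------------------------------------------------

def transition_matrix_loglik(C: np.ndarray, T: np.ndarray) -> float:
    """Multinomial log-likelihood sum_ij C_ij log T_ij (0 log 0 = 0)."""
    mask = C > 0
    if np.any(T[mask] <= 0):
        return -np.inf
    return float(np.sum(C[mask] * np.log(T[mask])))


def estimate_reversible(C: np.ndarray, tol: float = 1e-10,
                        max_iter: int = 1_000_000):
    """Maximum-likelihood reversible transition matrix from counts.

    Fixed-point iteration on the symmetric auxiliary variables x_ij
    (x_ij = x_ji, T_ij = x_ij / x_i):

        x_ij <- (c_ij + c_ji) / (c_i / x_i + c_j / x_j)

    iterated until the stationary distribution x_i / sum(x) changes by less
    than ``tol`` in the max norm.  Requires a strongly connected count graph
    with at least one outgoing count per state.

    Returns (T, pi, n_iter).
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    c_row = C.sum(axis=1)
    if np.any(c_row == 0):
        raise ValueError("every state needs at least one outgoing count")
    S = C + C.T
    mask = S > 0
    X = S.copy()
    X /= X.sum()
    pi = X.sum(axis=1)
    for it in range(1, max_iter + 1):
        x_i = X.sum(axis=1)
        q = c_row / x_i
        denom = q[:, None] + q[None, :]
        X_new = np.zeros_like(X)
        X_new[mask] = S[mask] / denom[mask]
        X_new /= X_new.sum()
        pi_new = X_new.sum(axis=1)
        delta = float(np.max(np.abs(pi_new - pi)))
        X, pi = X_new, pi_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"reversible estimator did not converge in {max_iter} iterations "
            f"(last max |delta pi| = {delta:.3e}, n = {n})"
        )
    T = X / X.sum(axis=1)[:, None]
    return T, pi, it


def _spectrum_reversible(T: np.ndarray, pi: np.ndarray):
    """Real sorted spectrum of a reversible T via the pi-symmetrized form."""
    sq = np.sqrt(pi)
    S = (sq[:, None] * T) / sq[None, :]
    S = 0.5 * (S + S.T)
    lams, U = np.linalg.eigh(S)
    order = np.argsort(lams)[::-1]
    lams, U = lams[order], U[:, order]
    if U[:, 0] @ sq < 0:
        U[:, 0] = -U[:, 0]
    right = U / sq[:, None]
    left = U * sq[:, None]
    # normalize the Perron pair to (ones, pi); degenerate Perron eigenvalue
    # (e.g. identity matrix) keeps the raw orthonormal basis
    scale = right[0, 0]
    if abs(scale) > 1e-300:
        right[:, 0] /= scale
        left[:, 0] *= scale
    return lams, left, right


# --------------------------------------------------------------------------
# model / results
# --------------------------------------------------------------------------

class MarkovStateModel:
    """MSM estimator over discrete microstate trajectories.

    Parameters
    ----------
    dtrajs : int array or list of int arrays
        Microstate index sequences (one per trajectory).
    lagtime : int
        Lag in frames at which transitions are counted.
    dt_ns : float
        Physical frame spacing (ns); the model lag is ``lagtime * dt_ns``.
    counting : {"sliding", "strided"}
    reversible : bool
        Fit under the detailed-balance constraint (default) or by plain row
        normalization.
    """

    def __init__(self, dtrajs, lagtime: int, dt_ns: float = 1.0,
                 counting: str = "sliding", reversible: bool = True,
                 n_states: int | None = None):
        self.dtrajs = _as_dtraj_list(dtrajs)
        self.lagtime = int(lagtime)
        self.dt_ns = float(dt_ns)
        self.counting = counting
        self.reversible = bool(reversible)
        self.n_states = n_states

    def fit(self) -> "MSMResults":
        cm = count_transitions(self.dtrajs, self.lagtime, self.counting,
                               self.n_states)
        active = largest_connected_set(cm)
        C = cm.counts[np.ix_(active, active)]
        if self.reversible:
            T, pi, n_iter = estimate_reversible(C)
            db = float(np.max(np.abs(pi[:, None] * T - (pi[:, None] * T).T)))
            lams, left, right = _spectrum_reversible(T, pi)
        else:
            T = C / C.sum(axis=1)[:, None]
            pi = stationary_distribution(T)
            n_iter = 0
            db = float(np.max(np.abs(pi[:, None] * T - (pi[:, None] * T).T)))
            vals, vecs = np.linalg.eig(T)
            order = np.argsort(-np.real(vals))
            lams = np.real_if_close(vals[order])
            right = np.real_if_close(vecs[:, order])
            left = None
        frames_total = sum(d.size for d in self.dtrajs)
        frames_active = sum(int(np.isin(d, active).sum()) for d in self.dtrajs)
        return MSMResults(
            lagtime=self.lagtime, dt_ns=self.dt_ns, counting=self.counting,
            reversible=self.reversible, count_matrix=cm, active_set=active,
            transition_matrix=T, stationary=pi, eigenvalues=np.real(lams),
            left_eigenvectors=left, right_eigenvectors=right,
            n_iter=n_iter, detailed_balance_violation=db,
            active_fraction=frames_active / frames_total,
            dtrajs=self.dtrajs,
        )


@dataclass
class MSMResults:
    """Fitted MSM: reversible transition matrix, spectrum and diagnostics.

    All state indices in the transition matrix refer to positions in
    ``active_set``; ``active_set[i]`` is the global microstate id.
    """

    lagtime: int
    dt_ns: float
    counting: str
    reversible: bool
    count_matrix: CountMatrix
    active_set: np.ndarray
    transition_matrix: np.ndarray
    stationary: np.ndarray
    eigenvalues: np.ndarray
    left_eigenvectors: np.ndarray | None
    right_eigenvectors: np.ndarray
    n_iter: int
    detailed_balance_violation: float
    active_fraction: float
    dtrajs: list[np.ndarray] = field(repr=False, default_factory=list)

    @classmethod
    def from_transition_matrix(cls, T, lagtime: int = 1, dt_ns: float = 1.0,
                               pi: np.ndarray | None = None) -> "MSMResults":
        """Exact results object for a known transition matrix (no data).

        Useful for analytic kinetics on hand-constructed chains.  ``pi``
        defaults to the leading left eigenvector; the matrix is assumed
        reversible for spectral analysis.
        """
        T = np.asarray(T, dtype=float)
        if pi is None:
            pi = stationary_distribution(T)
        lams, left, right = _spectrum_reversible(T, pi)
        db = float(np.max(np.abs(pi[:, None] * T - (pi[:, None] * T).T)))
        n = T.shape[0]
        return cls(lagtime=lagtime, dt_ns=dt_ns, counting="sliding",
                   reversible=True,
                   count_matrix=CountMatrix(lagtime, np.zeros((n, n))),
                   active_set=np.arange(n), transition_matrix=T,
                   stationary=pi, eigenvalues=lams, left_eigenvectors=left,
                   right_eigenvectors=right, n_iter=0,
                   detailed_balance_violation=db, active_fraction=1.0)

    @property
    def n_active(self) -> int:
        return self.active_set.size

    @property
    def lag_ns(self) -> float:
        return self.lagtime * self.dt_ns

    # -- index mapping -----------------------------------------------------
    def to_active(self, states) -> np.ndarray:
        """Map global microstate ids to active-set indices (drop inactive)."""
        lookup = {int(g): i for i, g in enumerate(self.active_set)}
        return np.asarray([lookup[int(s)] for s in states if int(s) in lookup],
                          dtype=np.int64)

    # -- spectrum ----------------------------------------------------------
    def timescales(self, m: int | None = None) -> np.ndarray:
        """Implied timescales t_i = -lag_ns / ln lambda_i (ns), below the
        stationary process.  Non-positive eigenvalues give NaN (below the
        resolution of the lag)."""
        lams = np.clip(self.eigenvalues[1:], -1 + 1e-12, 1 - 1e-12)
        if m is not None:
            lams = lams[:m]
        ts = np.full(lams.shape, np.nan)
        pos = lams > 0
        ts[pos] = -self.lag_ns / np.log(lams[pos])
        return ts

    def propagate(self, k: int) -> np.ndarray:
        return np.linalg.matrix_power(self.transition_matrix, k)

    # -- kinetics delegation ------------------------------------------------
    def mfpt(self, A, B, active_indices: bool = True) -> float:
        from .kinetics import mfpt as _mfpt
        A = A if active_indices else self.to_active(A)
        B = B if active_indices else self.to_active(B)
        return _mfpt(self, A, B)

    def committors(self, A, B):
        from .kinetics import committors as _committors
        return _committors(self, A, B)

    def pcca(self, m: int):
        from .coarse_grain import pcca as _pcca
        return _pcca(self, m)

    def ck_test(self, sets, multiples=(2, 3, 4, 5), n_boot: int = 100,
                seed: int = 0):
        return ck_test(self, self.dtrajs, sets, multiples, n_boot=n_boot,
                       seed=seed)

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        ts = self.timescales(5)
        lines = [
            "Markov state model",
            f"  lag: {self.lagtime} frames ({self.lag_ns:g} ns); counting: {self.counting}",
            f"  active microstates: {self.n_active} / {self.count_matrix.n_states} "
            f"({100 * self.active_fraction:.1f}% of frames)",
            f"  estimator: {'reversible ML' if self.reversible else 'row-normalized'}"
            + (f" ({self.n_iter} fixed-point iterations)" if self.reversible else ""),
            f"  max detailed-balance violation: {self.detailed_balance_violation:.2e}",
            "  implied timescales (ns): "
            + ", ".join("--" if not np.isfinite(t) else f"{t:.4g}" for t in ts),
        ]
        return "\n".join(lines)


# --------------------------------------------------------------------------
# implied timescales across lags
# --------------------------------------------------------------------------

@dataclass
class ITSResult:
    """Implied timescales as a function of lag (the Markovianity diagnostic:
    a well-chosen lag makes them flat in lag)."""

    lags: np.ndarray                 # frames
    dt_ns: float
    timescales_ns: np.ndarray        # (n_lags, m); NaN = below resolution
    active_sizes: np.ndarray
    m: int
    warnings_: list[str] = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd
        rows = []
        for i, lag in enumerate(self.lags):
            row = {"lag_frames": int(lag), "lag_ns": lag * self.dt_ns,
                   "n_active": int(self.active_sizes[i])}
            for j in range(self.m):
                row[f"t{j + 2}_ns"] = self.timescales_ns[i, j]
            rows.append(row)
        return pd.DataFrame(rows)


def implied_timescales(dtrajs, lags, m: int = 5, dt_ns: float = 1.0,
                       counting: str = "sliding",
                       reversible: bool = True) -> ITSResult:
    """Estimate one MSM per lag and report the top-m implied timescales."""
    lags = np.asarray(sorted(int(l) for l in lags))
    out = np.full((lags.size, m), np.nan)
    sizes = np.zeros(lags.size, dtype=int)
    warns: list[str] = []
    for i, lag in enumerate(lags):
        res = MarkovStateModel(dtrajs, int(lag), dt_ns=dt_ns, counting=counting,
                               reversible=reversible).fit()
        sizes[i] = res.n_active
        ts = res.timescales(m)
        out[i, : ts.size] = ts
    ref = sizes.max()
    for i, lag in enumerate(lags):
        if sizes[i] < 0.8 * ref:
            msg = (f"active set at lag {lag} has {sizes[i]} states "
                   f"vs {ref} at other lags")
            warns.append(msg)
            warnings.warn(msg)
    return ITSResult(lags=lags, dt_ns=dt_ns, timescales_ns=out,
                     active_sizes=sizes, m=m, warnings_=warns)


# --------------------------------------------------------------------------
# Chapman-Kolmogorov test
# --------------------------------------------------------------------------

@dataclass
class CKResult:
    """Chapman-Kolmogorov test: set-to-set transition probabilities
    re-estimated at lag k*tau versus predicted from T(tau)^k."""

    lagtime: int
    dt_ns: float
    multiples: list[int]
    sets: list[np.ndarray]           # global microstate ids per set
    predicted: dict[int, np.ndarray]
    estimated: dict[int, np.ndarray]
    stderr: dict[int, np.ndarray]
    flagged: list[int]
    n_boot: int

    @property
    def max_discrepancy(self) -> float:
        vals = [np.max(np.abs(self.estimated[k] - self.predicted[k]))
                for k in self.multiples if k not in self.flagged]
        return float(max(vals)) if vals else np.nan

    def max_z(self) -> float:
        """Largest |estimated - predicted| / bootstrap SE across pairs/multiples."""
        zs = []
        for k in self.multiples:
            if k in self.flagged:
                continue
            se = np.where(self.stderr[k] > 0, self.stderr[k], np.inf)
            zs.append(np.max(np.abs(self.estimated[k] - self.predicted[k]) / se))
        return float(max(zs)) if zs else np.nan

    def passed(self, z_threshold: float = 3.0) -> bool:
        return self.max_z() <= z_threshold


def _aggregate_sets(T: np.ndarray, pi: np.ndarray, sets_active: list[np.ndarray],
                    k: int = 1) -> np.ndarray:
    """pi-weighted set-to-set probabilities from T^k (rows normalized)."""
    Tk = np.linalg.matrix_power(T, k)
    m = len(sets_active)
    P = np.zeros((m, m))
    for a, A in enumerate(sets_active):
        w = pi[A] / pi[A].sum()
        for b, B in enumerate(sets_active):
            P[a, b] = float(w @ Tk[np.ix_(A, B)].sum(axis=1))
    return P


def _chunk(dtrajs: list[np.ndarray], n_chunks: int = 10) -> list[np.ndarray]:
    out = []
    for d in dtrajs:
        edges = np.linspace(0, d.size, n_chunks + 1).astype(int)
        out.extend(d[a:b] for a, b in zip(edges[:-1], edges[1:]) if b - a > 1)
    return out


def ck_test(msm: MSMResults, dtrajs, sets, multiples=(2, 3, 4, 5),
            n_boot: int = 100, seed: int = 0,
            reversible: bool = True) -> CKResult:
    """Chapman-Kolmogorov validation at the model's lag.

    ``sets`` partition the active set (global microstate ids; e.g. PCCA+
    macrostates).  For each multiple k the set-to-set probabilities of a
    freshly estimated MSM at lag k*tau ("estimated") are compared with the
    k-step propagation of the tested model ("predicted").  Error bars come
    from a trajectory-level bootstrap (single trajectories are first split
    into 10 contiguous chunks so resampling is possible).  Multiples whose
    re-estimation loses one of the sets entirely are flagged and skipped.
    """
    dtrajs = _as_dtraj_list(dtrajs)
    sets = [np.asarray(sorted(int(s) for s in S), dtype=np.int64) for S in sets]
    covered = np.sort(np.concatenate(sets))
    if not np.array_equal(covered, np.sort(self_active := msm.active_set)):
        missing = np.setdiff1d(self_active, covered)
        extra = np.setdiff1d(covered, self_active)
        if missing.size or np.unique(covered).size != covered.size:
            raise ValueError(
                f"sets must partition the active set (missing {missing.tolist()}, "
                f"duplicated/extra {extra.tolist()})"
            )
    sets_act = [msm.to_active(S) for S in sets]
    predicted = {int(k): _aggregate_sets(msm.transition_matrix, msm.stationary,
                                         sets_act, int(k))
                 for k in multiples}

    boot_pool = dtrajs if len(dtrajs) > 1 else _chunk(dtrajs)
    rng = np.random.default_rng(seed)

    def estimate_at(k: int, trajs) -> np.ndarray | None:
        lag_k = msm.lagtime * k
        if all(t.size <= lag_k for t in trajs):
            return None
        try:
            res = MarkovStateModel(trajs, lag_k, dt_ns=msm.dt_ns,
                                   counting=msm.counting,
                                   reversible=reversible,
                                   n_states=msm.count_matrix.n_states).fit()
        except (ValueError, RuntimeError):
            return None
        sets_k = [res.to_active(S) for S in sets]
        if any(s.size == 0 for s in sets_k):
            return None
        return _aggregate_sets(res.transition_matrix, res.stationary, sets_k)

    estimated, stderr, flagged = {}, {}, []
    for k in multiples:
        k = int(k)
        est = estimate_at(k, dtrajs)
        if est is None:
            flagged.append(k)
            estimated[k] = np.full_like(predicted[k], np.nan)
            stderr[k] = np.full_like(predicted[k], np.nan)
            warnings.warn(f"CK multiple {k}: insufficient counts at lag "
                          f"{msm.lagtime * k}; flagged")
            continue
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(boot_pool), len(boot_pool))
            r = estimate_at(k, [boot_pool[i] for i in idx])
            if r is not None:
                reps.append(r)
        se = (np.std(np.stack(reps), axis=0, ddof=1) if len(reps) > 1
              else np.full_like(est, np.nan))
        estimated[k], stderr[k] = est, se
    return CKResult(lagtime=msm.lagtime, dt_ns=msm.dt_ns,
                    multiples=[int(k) for k in multiples], sets=sets,
                    predicted=predicted, estimated=estimated, stderr=stderr,
                    flagged=flagged, n_boot=n_boot)
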