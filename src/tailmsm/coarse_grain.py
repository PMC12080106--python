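"""PCCA+ coarse-graining of microstates into metastable macrostates.

Robust Perron Cluster Cluster Analysis (PCCA+) writes the top-m right
eigenvectors of the transition matrix as a linear combination of m fuzzy
membership functions that are nonnegative and sum to one per microstate.
The transform is initialized from the inner simplex algorithm (the m
microstates spanning the largest simplex in eigenvector space become
candidate vertices) and then optimized over the feasible set to maximize
crispness, measured by the trace of the scaled overlap matrix
trace(diag(1/A[0]) A^T A).  Crisp macrostates are the argmax of the
membership rows (ties broken toward the lower macrostate index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .msm import MSMResults


@dataclass
class CoarseGrainedModel:
    """PCCA+ memberships and the induced crisp macrostate partition."""

    m: int
    memberships: np.ndarray          # (n_active, m), rows sum to 1
    crisp: np.ndarray                # (n_active,) macrostate index per microstate
    populations: np.ndarray          # (m,), pi aggregated through memberships
    active_set: np.ndarray           # global microstate ids (parallel to rows)

    def macrostate_sets(self, global_ids: bool = True) -> list[np.ndarray]:
        """Microstates of each macrostate (global ids by default)."""
        base = self.active_set if global_ids else np.arange(self.crisp.size)
        return [base[self.crisp == j] for j in range(self.m)]

    def coarse_transition_matrix(self, msm: MSMResults) -> np.ndarray:
        """Membership-aggregated set-to-set transition matrix (row-stochastic)."""
        pi = msm.stationary
        chi = self.memberships
        D = chi.T @ np.diag(pi) @ chi
        P = np.linalg.solve(D, chi.T @ np.diag(pi) @ msm.transition_matrix @ chi)
        return P / P.sum(axis=1)[:, None]


def _inner_simplex_vertices(X: np.ndarray) -> np.ndarray:
    """Indices of rows of X spanning a maximal simplex (inner simplex
    algorithm): start from the row of largest norm, then repeatedly take the
    row farthest from the affine span of the vertices found so far."""
    n, m = X.shape
    ortho = X.copy()
    verts = np.zeros(m, dtype=int)
    verts[0] = int(np.argmax(np.linalg.norm(ortho, axis=1)))
    ortho -= ortho[verts[0]]
    for j in range(1, m):
        d = np.linalg.norm(ortho, axis=1)
        verts[j] = int(np.argmax(d))
        if d[verts[j]] > 0:
            v = ortho[verts[j]] / d[verts[j]]
            ortho -= np.outer(ortho @ v, v)
    return verts


def _fill_A(A: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Reconstruct the constrained first row/column of A from its free block
    so that memberships chi = X A are nonnegative with unit row sums."""
    m = A.shape[0]
    A = A.copy()
    A[1:, 0] = -A[1:, 1:].sum(axis=1)
    for j in range(m):
        A[0, j] = -(X[:, 1:] @ A[1:, j]).min()
    s = A[0].sum()
    if s <= 0:
        raise FloatingPointError("infeasible PCCA+ transform (degenerate A)")
    return A / s


def _crispness(A: np.ndarray) -> float:
    return float(np.trace(np.diag(1.0 / A[0]) @ A.T @ A))


def pcca(msm: MSMResults, m: int, optimize: bool = True) -> CoarseGrainedModel:
    """PCCA+ fuzzy assignment of the model's microstates into m macrostates.

    Requires the top-m eigenvalues to be real and separated (a degenerate
    gap below 1e-10 raises, suggesting a different m).  Populations are
    pi aggregated through the memberships; the crisp map is the argmax
    membership with lowest-index tie-breaking.
    """
    if not (2 <= m <= msm.n_active):
        raise ValueError(f"m must be in [2, {msm.n_active}]")
    lams = msm.eigenvalues
    if m < lams.size and abs(lams[m - 1] - lams[m]) < 1e-10:
        raise ValueError(
            f"eigenvalues {m} and {m + 1} are degenerate "
            f"({lams[m - 1]:.12f} vs {lams[m]:.12f}); choose a different m"
        )
    X = msm.right_eigenvectors[:, :m].copy()
    X[:, 0] = 1.0  # Perron eigenvector is constant; enforce exactly
    if m == msm.n_active:
        chi = np.eye(m)  # every microstate is its own macrostate
    else:
        verts = _inner_simplex_vertices(X)
        A = np.linalg.inv(X[verts])
        try:
            A = _fill_A(A, X)
        except FloatingPointError:
            pass
        if optimize and m > 2:
            x0 = A[1:, 1:].flatten()

            def objective(alpha):
                Ac = A.copy()
                Ac[1:, 1:] = alpha.reshape(m - 1, m - 1)
                try:
                    Ac = _fill_A(Ac, X)
                except FloatingPointError:
                    return 1e10
                return -_crispness(Ac)

            res = minimize(objective, x0, method="Nelder-Mead",
                           options={"maxiter": 2000, "xatol": 1e-8,
                                    "fatol": 1e-10})
            A_try = A.copy()
            A_try[1:, 1:] = res.x.reshape(m - 1, m - 1)
            try:
                A_try = _fill_A(A_try, X)
                if _crispness(A_try) >= _crispness(A):
                    A = A_try
            except FloatingPointError:
                pass  # keep the unoptimized feasible transform
        chi = X @ A
        chi = np.clip(chi, 0.0, 1.0)
        chi /= chi.sum(axis=1)[:, None]
    crisp = np.argmax(chi, axis=1)  # argmax: lowest index on ties
    # relabel so every macrostate is nonempty under the crisp map
    present = np.unique(crisp)
    if present.size < m:
        raise ValueError(
            f"crisp map leaves macrostates {sorted(set(range(m)) - set(present))} "
            "empty; choose a smaller m"
        )
    pops = msm.stationary @ chi
    pops = pops / pops.sum()
    return CoarseGrainedModel(m=m, memberships=chi, crisp=crisp,
                              populations=pops, active_set=msm.active_set)


def choose_macrostate_count(msm: MSMResults, candidates,
                            dtrajs=None, ck_multiples=(2, 3),
                            n_boot: int = 25, seed: int = 0):
    """Diagnostics table over candidate macrostate counts.

    Per m: the spectral gap ratio lambda_m / lambda_{m+1}, the minimal
    crispness (smallest max-membership over microstates), and — when
    discrete trajectories are supplied — the maximal CK discrepancy at that
    m.  No automatic selection is made; the table is for the user.
    """
    import pandas as pd

    rows = []
    lams = msm.eigenvalues
    for m in candidates:
        m = int(m)
        row = {"m": m}
        row["gap_ratio"] = (float(lams[m - 1] / lams[m])
                            if m < lams.size and lams[m] > 0 else np.inf)
        try:
            cg = pcca(msm, m)
            row["min_crispness"] = float(np.max(cg.memberships, axis=1).min())
            if dtrajs is not None:
                ck = msm.ck_test(cg.macrostate_sets(), multiples=ck_multiples,
                                 n_boot=n_boot, seed=seed)
                row["ck_max_discrepancy"] = ck.max_discrepancy
        except ValueError as exc:
            row["min_crispness"] = np.nan
            row["note"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
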