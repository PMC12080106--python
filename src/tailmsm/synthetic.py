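"""Synthetic trajectory generators with known kinetic ground truth.

Every benchmark in this package runs against data whose kinetics are known
in closed form: discrete Markov chains with Gaussian emissions, overdamped
Langevin dynamics on multi-well potentials, and a toy polymer "tail" whose
backbone torsions switch between hidden conformational states.  The
:func:`oracle_kinetics` routine provides the exact stationary distribution,
eigenvalue spectrum, implied timescales and set-to-set mean first passage
times of the generating chain, so every estimator downstream can be checked
against analytic truth rather than against another estimator.

All generators take one explicit integer seed and use numpy's PCG64
generator; fixed seed implies bit-identical output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import breadth_first_order
from scipy import sparse


# --------------------------------------------------------------------------
# ground-truth Markov chain
# --------------------------------------------------------------------------

def _validate_stochastic(T: np.ndarray) -> None:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError(f"transition matrix must be square, got shape {T.shape}")
    if np.any(T < 0):
        i = int(np.argwhere(T < 0)[0, 0])
        raise ValueError(f"transition matrix has negative entries in row {i}")
    rowsums = T.sum(axis=1)
    bad = np.where(np.abs(rowsums - 1.0) > 1e-12)[0]
    if bad.size:
        raise ValueError(
            f"transition matrix rows {bad.tolist()} do not sum to 1 "
            f"(sums {rowsums[bad].tolist()})"
        )


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution pi solving pi T = pi, by leading left eigenvector."""
    T = np.asarray(T, dtype=float)
    vals, vecs = np.linalg.eig(T.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    pi /= pi.sum()
    resid = np.max(np.abs(pi @ T - pi))
    if resid > 1e-10:
        raise ValueError(f"stationary vector residual {resid:.2e} exceeds 1e-10")
    return pi


@dataclass(frozen=True)
class GroundTruthChain:
    """A discrete-time Markov chain used as generative kinetic truth.

    Parameters
    ----------
    transition_matrix
        Row-stochastic n x n matrix of per-step transition probabilities.
    lag_unit_ns
        Physical time represented by one chain step, in nanoseconds.
    seed
        Default seed for trajectory generation from this chain.
    """

    transition_matrix: np.ndarray
    lag_unit_ns: float = 1.0
    seed: int = 0
    stationary: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        T = np.asarray(self.transition_matrix, dtype=float)
        _validate_stochastic(T)
        if self.lag_unit_ns <= 0:
            raise ValueError("lag_unit_ns must be positive")
        object.__setattr__(self, "transition_matrix", T)
        object.__setattr__(self, "stationary", stationary_distribution(T))

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of T sorted by descending real part (lambda_1 = 1)."""
        vals = np.linalg.eigvals(self.transition_matrix)
        vals = np.real_if_close(vals, tol=1e6)
        return vals[np.argsort(-np.real(vals))]

    def implied_timescales(self, m: int | None = None) -> np.ndarray:
        """Exact implied timescales t_i = -lag/ln|lambda_i| (ns), i >= 2."""
        lams = np.real(self.eigenvalues())[1:]
        if m is not None:
            lams = lams[:m]
        out = np.full(lams.shape, np.nan)
        ok = np.abs(lams) > 0
        ok &= np.abs(lams) < 1
        out[ok] = -self.lag_unit_ns / np.log(np.abs(lams[ok]))
        return out


def generate_markov_chain(
    chain: GroundTruthChain,
    n_steps: int,
    seed: int | None = None,
    start: int | None = None,
) -> np.ndarray:
    """Simulate a state sequence of length ``n_steps`` from the chain.

    ``start`` defaults to a draw from the stationary distribution.  The
    sequence is bit-reproducible for a fixed seed (PCG64; one uniform per
    step, inverse-CDF over the cumulative row).
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    rng = np.random.default_rng(chain.seed if seed is None else seed)
    T = chain.transition_matrix
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0  # guard against round-off
    u = rng.random(n_steps)
    states = np.empty(n_steps, dtype=np.int64)
    if start is None:
        start = int(np.searchsorted(np.cumsum(chain.stationary), u[0]))
        start = min(start, chain.n_states - 1)
    s = int(start)
    states[0] = s
    for t in range(1, n_steps):
        s = int(np.searchsorted(cum[s], u[t], side="right"))
        states[t] = s
    return states


# --------------------------------------------------------------------------
# Gaussian emissions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EmissionModel:
    """Per-state Gaussian emission model mapping hidden states to features.

    ``feature_kinds`` tags each output dimension as ``"angle"`` or
    ``"distance"``.  Angle dimensions must come in consecutive (sin, cos)
    pairs; after noise is added, any pair falling outside the unit disk is
    radially clipped back onto it so the pair remains a valid circular
    encoding.
    """

    means: np.ndarray          # (n_states, d)
    covariances: np.ndarray    # (n_states, d, d)
    feature_kinds: tuple[str, ...] | None = None

    def __post_init__(self):
        means = np.atleast_2d(np.asarray(self.means, dtype=float))
        covs = np.asarray(self.covariances, dtype=float)
        if covs.ndim == 2:
            covs = covs[None, :, :]
        if covs.shape[0] != means.shape[0] or covs.shape[1:] != (means.shape[1],) * 2:
            raise ValueError(
                f"covariance shape {covs.shape} incompatible with means {means.shape}"
            )
        for s, c in enumerate(covs):
            if np.max(np.abs(c - c.T)) > 1e-12:
                raise ValueError(f"covariance of state {s} is not symmetric")
            if np.any(np.linalg.eigvalsh(c) < -1e-12):
                raise ValueError(f"covariance of state {s} is not positive semidefinite")
        kinds = self.feature_kinds
        if kinds is not None:
            if len(kinds) != means.shape[1]:
                raise ValueError("feature_kinds length must match feature dimension")
            i = 0
            while i < len(kinds):
                if kinds[i] == "angle":
                    if i + 1 >= len(kinds) or kinds[i + 1] != "angle":
                        raise ValueError("angle dimensions must come in (sin, cos) pairs")
                    i += 2
                else:
                    i += 1
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "covariances", covs)

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def emit_features(states: np.ndarray, model: EmissionModel, seed: int = 0) -> np.ndarray:
    """Draw one feature vector per frame from the frame's state Gaussian.

    Deterministic given seed: a single block of standard normals is drawn up
    front and coloured per state, so the output does not depend on state
    visit order bookkeeping.
    """
    states = np.asarray(states, dtype=np.int64)
    if states.min() < 0 or states.max() >= model.n_states:
        raise ValueError(
            f"state index {states.max()} outside emission model with "
            f"{model.n_states} states"
        )
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((states.size, model.n_features))
    out = np.empty_like(z)
    for s in range(model.n_states):
        mask = states == s
        if not mask.any():
            continue
        cov = model.covariances[s]
        if np.allclose(cov, 0):
            out[mask] = model.means[s]
        else:
            # square root via eigh tolerates singular covariances
            w, U = np.linalg.eigh(cov)
            L = U * np.sqrt(np.clip(w, 0, None))
            out[mask] = model.means[s] + z[mask] @ L.T
    if model.feature_kinds is not None:
        i = 0
        while i < model.n_features:
            if model.feature_kinds[i] == "angle":
                r = np.sqrt(out[:, i] ** 2 + out[:, i + 1] ** 2)
                over = r > 1.0
                if over.any():
                    out[over, i] /= r[over]
                    out[over, i + 1] /= r[over]
                i += 2
            else:
                i += 1
    return out


# --------------------------------------------------------------------------
# overdamped Langevin dynamics on multi-well potentials
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PotentialSpec:
    """Multi-well potential: a sum of inverted Gaussian wells.

    U(x) = -sum_i depth_i * exp(-|x - c_i|^2 / (2 w_i^2)), in units of kT=1
    when ``kT`` is 1.  Depths are well depths (positive numbers, kT units),
    widths set the well size.  A flat-bottom harmonic wall confines the
    walker: U gains 0.5 * wall_k * (|x| - confining_radius)^2 outside the
    confining radius (default: beyond the outermost well plus four widths),
    and is exactly the sum of Gaussian wells inside it.  The overdamped
    Euler-Maruyama step must satisfy sqrt(2 kT dt / friction) < min(width)/5
    so a single step cannot jump across a well.
    """

    dimension: int
    centers: np.ndarray        # (n_wells, dimension)
    depths: np.ndarray         # (n_wells,)
    widths: np.ndarray         # (n_wells,)
    kT: float = 1.0
    friction: float = 1.0
    dt: float = 0.01
    n_steps: int = 1000
    seed: int = 0
    confining_radius: float | None = None
    wall_k: float = 25.0

    def __post_init__(self):
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        depths = np.atleast_1d(np.asarray(self.depths, dtype=float))
        widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        if self.dimension not in (1, 2):
            raise ValueError("dimension must be 1 or 2")
        if centers.shape != (depths.size, self.dimension):
            raise ValueError("centers must be (n_wells, dimension)")
        if depths.size < 2:
            raise ValueError("at least 2 wells required")
        if np.any(widths <= 0):
            raise ValueError("well widths must be positive")
        step_sd = math.sqrt(2.0 * self.kT * self.dt / self.friction)
        if self.kT > 0 and step_sd >= widths.min() / 5.0:
            raise ValueError(
                f"per-step displacement stdev {step_sd:.3g} must be below "
                f"min well width / 5 = {widths.min() / 5.0:.3g}; reduce dt"
            )
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "widths", widths)
        if self.confining_radius is None:
            radius = float(np.max(np.linalg.norm(centers, axis=1))
                           + 4.0 * widths.max())
            object.__setattr__(self, "confining_radius", radius)

    def potential(self, x: np.ndarray) -> np.ndarray:
        """U(x) for points x of shape (..., dimension), in kT-at-kT=1 units."""
        x = np.asarray(x, dtype=float).reshape(-1, self.dimension)
        d2 = ((x[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        U = -(self.depths * np.exp(-d2 / (2.0 * self.widths**2))).sum(axis=1)
        r = np.linalg.norm(x, axis=1)
        over = np.clip(r - self.confining_radius, 0.0, None)
        return U + 0.5 * self.wall_k * over**2

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float).reshape(-1, self.dimension)
        diff = x[:, None, :] - self.centers[None, :, :]
        d2 = (diff**2).sum(axis=2)
        g = self.depths / self.widths**2 * np.exp(-d2 / (2.0 * self.widths**2))
        grad = (g[:, :, None] * diff).sum(axis=1)
        r = np.linalg.norm(x, axis=1)
        out = r > self.confining_radius
        if out.any():
            grad[out] += (self.wall_k * (r[out] - self.confining_radius)
                          / r[out])[:, None] * x[out]
        return grad


def generate_langevin(spec: PotentialSpec, seed: int | None = None) -> np.ndarray:
    """Overdamped Euler-Maruyama trajectory on the spec's potential.

    x <- x - (grad U / friction) dt + sqrt(2 kT dt / friction) * xi.
    Returns an (n_steps, dimension) array; raises if the walker leaves the
    simulation domain (divergence), advising a smaller time step.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n, dim = spec.n_steps, spec.dimension
    noise_sd = math.sqrt(2.0 * spec.kT * spec.dt / spec.friction)
    xi = rng.standard_normal((n, dim)) if noise_sd > 0 else np.zeros((n, dim))
    bound = spec.confining_radius + 20.0 * np.max(spec.widths)
    x = spec.centers[0].astype(float).copy()
    out = np.empty((n, dim))
    out[0] = x
    dt_over_g = spec.dt / spec.friction
    # loop-local gradient of the Gaussian wells + confining wall
    centers = spec.centers
    inv2w2 = 1.0 / (2.0 * spec.widths**2)
    dw = spec.depths / spec.widths**2
    radius, wall_k = spec.confining_radius, spec.wall_k
    for t in range(1, n):
        diff = x - centers
        d2 = (diff * diff).sum(axis=1)
        g = (dw * np.exp(-d2 * inv2w2)) @ diff
        r2 = float(x @ x)
        if r2 > radius * radius:
            r = math.sqrt(r2)
            g = g + (wall_k * (r - radius) / r) * x
        x = x - g * dt_over_g + noise_sd * xi[t]
        if float(x @ x) > bound * bound:
            raise FloatingPointError(
                f"Langevin trajectory diverged at step {t} (|x| > {bound:.3g}); "
                "use a smaller time step"
            )
        out[t] = x
    return out


# --------------------------------------------------------------------------
# toy polymer tail
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyTailSpec:
    """A bead-chain polymer whose torsions follow hidden metastable states.

    Each frame is a 3D chain of ``n_residues`` beads with fixed bond length,
    fixed 90-degree planar bond angles, and backbone torsions drawn from a
    von Mises distribution whose circular mean and concentration depend on
    the hidden state of a generative Markov chain.  This isolates exactly
    the two feature classes the analysis pipeline consumes: backbone
    torsions and pairwise bead distances.
    """

    n_residues: int
    torsion_means: np.ndarray          # (n_states,) circular means, radians
    torsion_concentrations: np.ndarray  # (n_states,) von Mises kappa
    chain: GroundTruthChain
    bond_length: float = 3.8            # Angstrom, CA-CA virtual bond
    seed: int = 0

    def __post_init__(self):
        means = np.atleast_1d(np.asarray(self.torsion_means, dtype=float))
        kappas = np.atleast_1d(np.asarray(self.torsion_concentrations, dtype=float))
        if self.n_residues < 4:
            raise ValueError("n_residues must be >= 4 (need at least one torsion)")
        if means.size != self.chain.n_states or kappas.size != self.chain.n_states:
            raise ValueError("need one torsion (mean, concentration) per hidden state")
        if np.any(kappas <= 0):
            raise ValueError("torsion concentrations must be > 0")
        if self.bond_length <= 0:
            raise ValueError("bond length must be positive")
        object.__setattr__(self, "torsion_means", means)
        object.__setattr__(self, "torsion_concentrations", kappas)


def _build_chain_frames(torsions: np.ndarray, bond_length: float) -> np.ndarray:
    """Place beads from torsions with 90-degree bond angles (vectorized NeRF).

    torsions: (frames, n_res - 3).  Returns (frames, n_res, 3).
    """
    n_frames, n_tor = torsions.shape
    n_res = n_tor + 3
    b = bond_length
    xyz = np.zeros((n_frames, n_res, 3))
    xyz[:, 1] = (b, 0.0, 0.0)
    xyz[:, 2] = (b, b, 0.0)  # 90-degree angle at bead 1
    for i in range(3, n_res):
        A, B, C = xyz[:, i - 3], xyz[:, i - 2], xyz[:, i - 1]
        bc = C - B
        bc /= np.linalg.norm(bc, axis=1, keepdims=True)
        n = np.cross(B - A, bc)
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        m = np.cross(n, bc)
        phi = torsions[:, i - 3]
        # bond angle fixed at 90 degrees: cos = 0, sin = 1
        d = (np.cos(phi)[:, None] * m + np.sin(phi)[:, None] * n) * b
        xyz[:, i] = C + d
    return xyz


def generate_toy_tail(
    spec: ToyTailSpec, n_frames: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the toy tail; returns (coords (frames, n_res, 3) in A, hidden states)."""
    seed = spec.seed if seed is None else seed
    states = generate_markov_chain(spec.chain, n_frames, seed=seed)
    rng = np.random.default_rng(seed + 1)
    n_tor = spec.n_residues - 3
    mu = spec.torsion_means[states][:, None]
    kappa = spec.torsion_concentrations[states][:, None]
    torsions = rng.vonmises(mu, np.broadcast_to(kappa, (n_frames, n_tor)))
    coords = _build_chain_frames(torsions, spec.bond_length)
    return coords, states


# --------------------------------------------------------------------------
# analytic kinetic oracles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OracleKinetics:
    """Exact kinetic quantities of a ground-truth chain for one (A, B) pair."""

    mfpt_ns: float
    mfpt_per_state_ns: np.ndarray
    eigenvalues: np.ndarray
    implied_timescales_ns: np.ndarray
    reachable: bool


def exact_mfpt(T: np.ndarray, pi: np.ndarray, A, B, lag_unit: float = 1.0) -> tuple[float, np.ndarray, bool]:
    """MFPT into set B, pi-weighted over A, from the absorbing-chain linear solve.

    Solves (I - T_CC) m_C = 1 on C = complement of B; returns time in units
    of ``lag_unit`` per step.  Unreachable B gives (inf, ..., False).
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    A = np.asarray(sorted(set(int(a) for a in A)))
    B = np.asarray(sorted(set(int(b) for b in B)))
    if A.size == 0 or B.size == 0:
        raise ValueError("A and B must be nonempty")
    if np.intersect1d(A, B).size:
        raise ValueError("A and B must be disjoint")
    # reachability of B from A along positive-probability edges
    adj = sparse.csr_matrix(T > 0)
    reach = set()
    for a in A:
        order = breadth_first_order(adj, int(a), return_predecessors=False)
        reach.update(int(v) for v in np.atleast_1d(order))
    if not reach.intersection(B.tolist()):
        warnings.warn("sink set B unreachable from source set A: MFPT is infinite")
        return math.inf, np.full(n, np.inf), False
    C = np.setdiff1d(np.arange(n), B)
    m = np.zeros(n)
    M = np.eye(C.size) - T[np.ix_(C, C)]
    m[C] = np.linalg.solve(M, np.ones(C.size))
    w = pi[A] / pi[A].sum()
    return float(w @ m[A]) * lag_unit, m * lag_unit, True


def oracle_kinetics(chain: GroundTruthChain, A, B) -> OracleKinetics:
    """Exact MFPT (ns), eigenvalue spectrum and implied timescales of the chain."""
    mfpt, per_state, reachable = exact_mfpt(
        chain.transition_matrix, chain.stationary, A, B, chain.lag_unit_ns
    )
    return OracleKinetics(
        mfpt_ns=mfpt,
        mfpt_per_state_ns=per_state,
        eigenvalues=chain.eigenvalues(),
        implied_timescales_ns=chain.implied_timescales(),
        reachable=reachable,
    )
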