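"""Time-lagged independent component analysis and free-energy surfaces.

tICA finds the linear combinations of input features with the largest
autocorrelation at a chosen lag by solving the generalized eigenproblem
C_tau v = lambda C_0 v on instantaneous and time-lagged covariances.  The
leading independent components (ICs) are the slowest collective coordinates
of the data and are the space in which microstates are defined downstream.

The model follows the fit/results convention: ``TICA(features, lag).fit()``
returns a :class:`TICAResults` carrying eigenvalues, projection vectors and
diagnostics, with ``transform`` and ``summary`` on the results object.

Covariances are estimated in symmetrized (reversible) form: both the mean
and the covariances average over the forward and time-reversed lagged
pairs, the standard remedy for finite-sampling non-reversibility and the
estimator consistent with the reversible Markov model fitted afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._linalg import regularized_inverse_sqrt, roundoff_floor
from .featurization import FeatureTrajectory

GAS_CONSTANT_KCAL = 0.0019872  # kcal / (mol K)


def _as_arrays(features) -> list[np.ndarray]:
    seq = features if isinstance(features, (list, tuple)) else [features]
    return [f.values if isinstance(f, FeatureTrajectory) else np.atleast_2d(np.asarray(f, float))
            for f in seq]


class TICA:
    """tICA model over one or more feature trajectories.

    Parameters
    ----------
    features : FeatureTrajectory or array or list thereof
        Input trajectories; lagged pairs never span trajectory boundaries.
    lag : int
        Lag in frames.
    dt_ns : float, optional
        Frame spacing in ns; taken from the first FeatureTrajectory if not
        given.
    epsilon : float
        Relative eigenvalue cutoff for covariance regularization.
    """

    def __init__(self, features, lag: int, dt_ns: float | None = None,
                 epsilon: float = 1e-10):
        self.trajs = _as_arrays(features)
        if lag < 1:
            raise ValueError("lag must be >= 1")
        short = [i for i, t in enumerate(self.trajs) if t.shape[0] <= lag]
        if short:
            raise ValueError(
                f"lag {lag} is not shorter than trajectories {short}"
            )
        self.lag = int(lag)
        if dt_ns is None:
            f0 = features[0] if isinstance(features, (list, tuple)) else features
            dt_ns = f0.dt_ns if isinstance(f0, FeatureTrajectory) else 1.0
        self.dt_ns = float(dt_ns)
        self.epsilon = float(epsilon)

    def fit(self, n_components: int | None = None,
            var_cutoff: float = 0.95) -> "TICAResults":
        X0 = np.vstack([t[:-self.lag] for t in self.trajs])
        Xt = np.vstack([t[self.lag:] for t in self.trajs])
        n, d = X0.shape
        if 2 * n < 2 * d:
            raise ValueError("too few lagged pairs for the feature dimension")
        mean = 0.5 * (X0.mean(axis=0) + Xt.mean(axis=0))
        A = X0 - mean
        B = Xt - mean
        C0 = (A.T @ A + B.T @ B) / (2.0 * n)
        Ctau = (A.T @ B + B.T @ A) / (2.0 * n)
        W = regularized_inverse_sqrt(C0, self.epsilon,
                                     roundoff_floor(np.vstack([X0, Xt])))  # (d, r)
        M = W.T @ Ctau @ W
        M = 0.5 * (M + M.T)
        lams, V = np.linalg.eigh(M)
        order = np.argsort(lams)[::-1]
        lams, V = lams[order], V[:, order]
        lams = np.minimum(lams, 1.0)  # symmetrized finite-sample estimates can graze 1
        vectors = W @ V                                          # C0-orthonormal
        if n_components is None:
            kin = lams**2
            frac = np.cumsum(kin) / kin.sum()
            n_components = int(np.searchsorted(frac, var_cutoff) + 1)
        n_components = min(n_components, lams.size)
        return TICAResults(
            lag=self.lag, dt_ns=self.dt_ns, mean=mean, c0=C0, ctau=Ctau,
            eigenvalues=lams, projection=vectors,
            n_components=n_components,
        )


@dataclass
class TICAResults:
    """Fitted tICA estimates: spectrum, projection vectors, diagnostics."""

    lag: int
    dt_ns: float
    mean: np.ndarray
    c0: np.ndarray
    ctau: np.ndarray
    eigenvalues: np.ndarray        # descending, clipped to <= 1
    projection: np.ndarray         # (d, r), C0-orthonormal columns
    n_components: int

    @property
    def lag_ns(self) -> float:
        return self.lag * self.dt_ns

    def timescales(self, m: int | None = None) -> np.ndarray:
        """Relaxation timescales t_i = -lag_ns / ln lambda_i (ns)."""
        lams = np.clip(self.eigenvalues, -1 + 1e-12, 1 - 1e-12)
        ts = np.full(lams.shape, np.nan)
        pos = lams > 0
        ts[pos] = -self.lag_ns / np.log(lams[pos])
        return ts if m is None else ts[:m]

    def kinetic_variance_fraction(self) -> np.ndarray:
        kin = self.eigenvalues**2
        return np.cumsum(kin) / kin.sum()

    def transform(self, features, n_components: int | None = None):
        """Project feature trajectories onto the leading ICs.

        Returns one (frames, m) array per input trajectory (or a single
        array for a single input).  IC1 is the slowest component; projected
        training data have unit variance per component (C0-normalization).
        """
        m = self.n_components if n_components is None else n_components
        trajs = _as_arrays(features)
        P = self.projection[:, :m]
        out = []
        for t in trajs:
            if t.shape[1] != self.mean.size:
                raise ValueError(
                    f"feature dimension {t.shape[1]} does not match fitted "
                    f"dimension {self.mean.size}"
                )
            out.append((t - self.mean) @ P)
        return out if isinstance(features, (list, tuple)) else out[0]

    def summary(self) -> str:
        lines = [
            "tICA results",
            f"  lag: {self.lag} frames ({self.lag_ns:g} ns)",
            f"  feature dimension: {self.mean.size}; retained components: {self.n_components}",
            "  i   eigenvalue   timescale (ns)   cum. kinetic var",
        ]
        ts = self.timescales()
        frac = self.kinetic_variance_fraction()
        for i in range(min(10, self.eigenvalues.size)):
            t = f"{ts[i]:.3g}" if np.isfinite(ts[i]) else "--"
            lines.append(
                f"  {i + 1:<3d} {self.eigenvalues[i]:>10.4f}   {t:>12}   {frac[i]:>10.3f}"
            )
        return "\n".join(lines)


# --------------------------------------------------------------------------
# free-energy surface
# --------------------------------------------------------------------------

@dataclass
class FreeEnergySurface:
    """2D free-energy surface Delta G(x, y) = -RT ln[P(x, y) / Pmax].

    ``probability`` is the normalized 2D histogram mass (sums to 1);
    ``delta_g`` is in kcal/mol with its minimum exactly 0 at the most
    populated bin; empty bins are NaN (masked).
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    probability: np.ndarray
    delta_g: np.ndarray
    temperature: float
    gas_constant: float = GAS_CONSTANT_KCAL

    @property
    def p_max(self) -> float:
        return float(np.nanmax(self.probability))

    def barrier_between(self, point_a, point_b) -> float:
        """Delta G of the highest point on the straight path between two
        (x, y) points, relative to the lower of the two endpoint basins."""
        xa = np.linspace(point_a[0], point_b[0], 200)
        ya = np.linspace(point_a[1], point_b[1], 200)
        ix = np.clip(np.searchsorted(self.x_edges, xa) - 1, 0, self.delta_g.shape[0] - 1)
        iy = np.clip(np.searchsorted(self.y_edges, ya) - 1, 0, self.delta_g.shape[1] - 1)
        prof = self.delta_g[ix, iy]
        prof = prof[np.isfinite(prof)]
        return float(np.max(prof) - min(prof[0], prof[-1]))


def free_energy_surface(ic1, ic2, n_bins: int = 60,
                        temperature: float = 310.0,
                        gas_constant: float = GAS_CONSTANT_KCAL,
                        bins=None) -> FreeEnergySurface:
    """Histogram two coordinates into a free-energy surface.

    Delta G(x,y) = -RT ln[P(x,y)/Pmax] with R in kcal/(mol K) and T in K,
    so Delta G is in kcal/mol and equals exactly 0 at the most populated
    bin.  Bins never visited are masked as NaN.
    """
    ic1 = np.ravel(np.asarray(ic1, float))
    ic2 = np.ravel(np.asarray(ic2, float))
    if ic1.size < 1 or ic1.size != ic2.size:
        raise ValueError("ic1 and ic2 must be equal-length, nonempty")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    H, xe, ye = np.histogram2d(ic1, ic2, bins=bins if bins is not None else n_bins)
    P = H / H.sum()
    RT = gas_constant * temperature
    with np.errstate(divide="ignore"):
        dg = -RT * np.log(P / P.max())
    dg[P == 0] = np.nan
    return FreeEnergySurface(xe, ye, P, dg, temperature, gas_constant)
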