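"""Featurization of coordinate trajectories and VAMP-2 feature scoring.

Converts bead/atom coordinate trajectories into the two feature classes the
kinetic analysis uses — backbone torsions (optionally circularly encoded as
sin/cos pairs) and pairwise distances — and scores candidate feature sets by
the VAMP-2 criterion, the sum of squared singular values of the estimated
propagator, which quantifies how much kinetic variance a feature set
captures at a given lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._linalg import regularized_inverse_sqrt, roundoff_floor


@dataclass
class FeatureTrajectory:
    """Time-ordered feature vectors from one contiguous trajectory.

    values : (frames, d) array, no missing values
    labels : one name per feature column
    dt_ns  : frame spacing in nanoseconds
    traj_id: identifier of the source trajectory
    """

    values: np.ndarray
    labels: list[str] = field(default_factory=list)
    dt_ns: float = 1.0
    traj_id: str = "traj-0"

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not self.labels:
            self.labels = [f"f{i}" for i in range(self.values.shape[1])]
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("one label required per feature column")
        if self.values.shape[0] < 2:
            raise ValueError("feature trajectory needs at least 2 frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"trajectory {self.traj_id} contains non-finite values")
        if self.dt_ns <= 0:
            raise ValueError("frame spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FeatureSetDefinition:
    """A named recipe of torsion quadruplets and distance pairs.

    ``encoding`` controls how torsion angles enter the feature matrix:
    ``"sincos"`` (default) maps each angle to a (sin, cos) pair, continuous
    across the +/-pi seam; ``"raw"`` keeps the signed angle in radians.
    """

    torsions: tuple[tuple[int, int, int, int], ...] = ()
    distance_pairs: tuple[tuple[int, int], ...] = ()
    encoding: str = "sincos"

    def __post_init__(self):
        for q in self.torsions:
            if len(set(q)) != 4:
                raise ValueError(f"torsion quadruplet {q} must have 4 distinct indices")
        for p in self.distance_pairs:
            if p[0] == p[1]:
                raise ValueError(f"distance pair {p} has equal indices")
        if self.encoding not in ("sincos", "raw"):
            raise ValueError("encoding must be 'sincos' or 'raw'")

    def validate_indices(self, n_atoms: int) -> None:
        idx = [i for q in self.torsions for i in q] + [
            i for p in self.distance_pairs for i in p
        ]
        if idx and (min(idx) < 0 or max(idx) >= n_atoms):
            raise ValueError(f"feature indices outside chain of length {n_atoms}")


def backbone_feature_set(n_atoms: int, encoding: str = "sincos",
                         min_separation: int = 3) -> FeatureSetDefinition:
    """All consecutive torsion quadruplets plus all pairs >= min_separation apart."""
    torsions = tuple((i, i + 1, i + 2, i + 3) for i in range(n_atoms - 3))
    pairs = tuple(
        (i, j) for i in range(n_atoms) for j in range(i + min_separation, n_atoms)
    )
    return FeatureSetDefinition(torsions=torsions, distance_pairs=pairs,
                                encoding=encoding)


# --------------------------------------------------------------------------
# geometric features
# --------------------------------------------------------------------------

def compute_dihedrals(coords: np.ndarray, quadruplets,
                      on_collinear: str = "nan") -> np.ndarray:
    """Signed dihedral angles in (-pi, pi] for each quadruplet and frame.

    Uses the atan2 form of the two-plane-normal construction, which is
    invariant under rigid-body motion.  Collinear triples (a vanishing plane
    normal) yield NaN with a warning by default, or raise when
    ``on_collinear="raise"``.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    quads = np.asarray(list(quadruplets), dtype=int)
    if quads.size == 0:
        return np.empty((coords.shape[0], 0))
    p0, p1, p2, p3 = (coords[:, quads[:, k], :] for k in range(4))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    x = (n1 * n2).sum(axis=-1)
    y = (np.cross(n1, n2) * (b2 / np.where(b2n[..., None] == 0, 1, b2n[..., None]))).sum(axis=-1)
    degenerate = (np.linalg.norm(n1, axis=-1) < 1e-12) | (
        np.linalg.norm(n2, axis=-1) < 1e-12
    )
    if degenerate.any():
        if on_collinear == "raise":
            raise ValueError("collinear atom triple encountered in dihedral computation")
        warnings.warn(
            f"{int(degenerate.sum())} dihedral value(s) undefined (collinear atoms); "
            "set to NaN"
        )
    angles = np.arctan2(y, x)
    # map -pi to +pi so the range is (-pi, pi]
    angles[angles == -np.pi] = np.pi
    angles[degenerate] = np.nan
    return angles


def encode_torsions(angles: np.ndarray) -> np.ndarray:
    """Map each angle column theta to the (sin theta, cos theta) pair."""
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    out = np.empty((angles.shape[0], 2 * angles.shape[1]))
    out[:, 0::2] = np.sin(angles)
    out[:, 1::2] = np.cos(angles)
    return out


def compute_pairwise_distances(coords: np.ndarray, pairs) -> np.ndarray:
    """Euclidean distances (same length unit as coords) per pair and frame."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    pairs = np.asarray(list(pairs), dtype=int)
    if pairs.size == 0:
        return np.empty((coords.shape[0], 0))
    if np.any(pairs[:, 0] == pairs[:, 1]):
        bad = pairs[pairs[:, 0] == pairs[:, 1]][0]
        raise ValueError(f"distance pair {tuple(bad)} has equal indices")
    diff = coords[:, pairs[:, 0], :] - coords[:, pairs[:, 1], :]
    return np.linalg.norm(diff, axis=-1)


def featurize(coords: np.ndarray, definition: FeatureSetDefinition,
              dt_ns: float = 1.0, traj_id: str = "traj-0") -> FeatureTrajectory:
    """Apply a feature-set definition to one coordinate trajectory."""
    coords = np.asarray(coords, dtype=float)
    definition.validate_indices(coords.shape[1])
    blocks, labels = [], []
    if definition.torsions:
        ang = compute_dihedrals(coords, definition.torsions)
        if definition.encoding == "sincos":
            blocks.append(encode_torsions(ang))
            for q in definition.torsions:
                labels += [f"sin_phi{q}", f"cos_phi{q}"]
        else:
            blocks.append(ang)
            labels += [f"phi{q}" for q in definition.torsions]
    if definition.distance_pairs:
        blocks.append(compute_pairwise_distances(coords, definition.distance_pairs))
        labels += [f"d{p}" for p in definition.distance_pairs]
    if not blocks:
        raise ValueError("feature set definition is empty")
    return FeatureTrajectory(np.hstack(blocks), labels, dt_ns, traj_id)


def combine_features(parts: list[FeatureTrajectory]) -> FeatureTrajectory:
    """Column-concatenate feature blocks of the same trajectory."""
    parts = [p for p in parts if p.n_features > 0]
    if not parts:
        raise ValueError("no non-empty feature blocks to combine")
    first = parts[0]
    for p in parts[1:]:
        if p.n_frames != first.n_frames:
            raise ValueError(
                f"frame count mismatch: {first.traj_id} has {first.n_frames}, "
                f"{p.traj_id} has {p.n_frames}"
            )
        if abs(p.dt_ns - first.dt_ns) > 1e-12:
            raise ValueError("frame spacings differ between blocks")
    values = np.hstack([p.values for p in parts])
    labels = [lab for p in parts for lab in p.labels]
    return replace(first, values=values, labels=labels)


# --------------------------------------------------------------------------
# VAMP-2 scoring
# --------------------------------------------------------------------------

def _lagged_blocks(trajs: list[np.ndarray], lag: int):
    X0 = np.vstack([t[:-lag] for t in trajs if t.shape[0] > lag])
    Xt = np.vstack([t[lag:] for t in trajs if t.shape[0] > lag])
    if X0.shape[0] == 0:
        raise ValueError(f"no usable frame pairs at lag {lag}")
    return X0, Xt


def vamp2_score(features, lag: int, dim: int | None = None,
                epsilon: float = 1e-10) -> float:
    """VAMP-2 score of a feature set at a given lag (frames).

    Sum of squared singular values of the half-weighted propagator matrix
    C00^{-1/2} C0t Ctt^{-1/2}, counting the constant singular function, so
    the score is >= 1 and bounded by ``dim``.  ``dim`` limits the number of
    singular functions counted (constant included); ``None`` keeps all.
    Near-singular covariances are regularized by truncating eigenvalues
    below ``epsilon`` times the largest.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    trajs = [f.values if isinstance(f, FeatureTrajectory) else np.atleast_2d(np.asarray(f, float))
             for f in (features if isinstance(features, (list, tuple)) else [features])]
    X0, Xt = _lagged_blocks(trajs, lag)
    n, d = X0.shape
    if n < 10 * d:
        warnings.warn(
            f"only {n} frame pairs for {d} features; VAMP-2 estimate may be unstable"
        )
    X0c = X0 - X0.mean(axis=0)
    Xtc = Xt - Xt.mean(axis=0)
    C00 = X0c.T @ X0c / n
    Ctt = Xtc.T @ Xtc / n
    C0t = X0c.T @ Xtc / n
    floor = roundoff_floor(np.vstack([X0, Xt]))
    W0 = regularized_inverse_sqrt(C00, epsilon, floor)
    Wt = regularized_inverse_sqrt(Ctt, epsilon, floor)
    K = W0.T @ C0t @ Wt
    s = np.linalg.svd(K, compute_uv=False)
    if dim is not None:
        if dim < 1:
            raise ValueError("dim must be >= 1")
        s = s[: dim - 1]  # the constant function occupies one slot
    return float(1.0 + np.sum(s**2))


def _contiguous_splits(traj: np.ndarray, n_splits: int) -> list[np.ndarray]:
    edges = np.linspace(0, traj.shape[0], n_splits + 1).astype(int)
    return [traj[a:b] for a, b in zip(edges[:-1], edges[1:]) if b - a > 1]


def rank_feature_sets(coords_list, candidates: dict[str, FeatureSetDefinition],
                      lags, dim: int | None = None, n_splits: int = 3,
                      dt_ns: float = 1.0) -> pd.DataFrame:
    """Score named feature sets across lags with contiguous-block splits.

    Each trajectory is cut into ``n_splits`` contiguous blocks (preserving
    temporal correlation within blocks); the VAMP-2 score is computed per
    block and summarized as mean +/- standard error.  Returns a tidy table
    with one row per (feature set, lag) and a rank column per lag
    (1 = highest mean score).
    """
    coords_list = [np.asarray(c, float) for c in
                   (coords_list if isinstance(coords_list, (list, tuple)) else [coords_list])]
    rows = []
    for name, definition in candidates.items():
        ftrajs = [featurize(c, definition, dt_ns, f"traj-{i}").values
                  for i, c in enumerate(coords_list)]
        for lag in lags:
            blocks = [b for t in ftrajs for b in _contiguous_splits(t, n_splits)]
            scores = [vamp2_score([b], lag, dim=dim) for b in blocks if b.shape[0] > lag]
            scores = np.asarray(scores)
            rows.append({
                "feature_set": name,
                "lag": int(lag),
                "score_mean": float(scores.mean()),
                "score_stderr": float(scores.std(ddof=1) / np.sqrt(scores.size))
                if scores.size > 1 else 0.0,
                "n_splits": int(scores.size),
            })
    table = pd.DataFrame(rows)
    table["rank"] = table.groupby("lag")["score_mean"].rank(
        ascending=False, method="min").astype(int)
    return table.sort_values(["lag", "rank"]).reset_index(drop=True)
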