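"""k-means discretization of the reduced (tICA) space into microstates.

Lloyd iterations from k-means++ seeding, deterministic for a fixed seed.
The loop is explicit so the estimator can expose the per-iteration inertia
history (which must be non-increasing), a documented empty-cluster rule
(re-seed from the point farthest from its assigned center) and a
deterministic tie rule (nearest center, lowest index on ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus


@dataclass
class ClusteringModel:
    """Fitted k-means microstate model."""

    k: int
    centers: np.ndarray
    seed: int
    inertia: float
    inertia_history: list[float] = field(default_factory=list, repr=False)
    n_iter: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("cluster centers must be finite")


def fit_kmeans(reduced: np.ndarray, k: int, seed: int = 0,
               tol: float = 1e-6, max_iter: int = 500) -> ClusteringModel:
    """Cluster frames into ``k`` microstates.

    Raises if there are fewer frames than centers.  Iterates until the
    maximum center shift drops below ``tol`` or ``max_iter`` is reached.
    """
    X = np.atleast_2d(np.asarray(reduced, dtype=float))
    if X.shape[0] < k:
        raise ValueError(f"{X.shape[0]} frames < k = {k} clusters")
    centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=seed)
    history: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        D = cdist(X, centers)
        labels = np.argmin(D, axis=1)            # argmin: lowest index on ties
        point_d2 = D[np.arange(X.shape[0]), labels] ** 2
        inertia = float(point_d2.sum())
        if history and inertia > history[-1] + 1e-9 * max(1.0, history[-1]):
            raise RuntimeError("k-means inertia increased between iterations")
        history.append(inertia)
        new_centers = centers.copy()
        for j in range(k):
            mask = labels == j
            if mask.any():
                new_centers[j] = X[mask].mean(axis=0)
            else:
                # empty cluster: re-seed from the point farthest from its center
                far = int(np.argmax(point_d2))
                new_centers[j] = X[far]
                point_d2[far] = 0.0
        shift = float(np.max(np.linalg.norm(new_centers - centers, axis=1)))
        centers = new_centers
        if shift < tol:
            break
    D = cdist(X, centers)
    labels = np.argmin(D, axis=1)
    inertia = float((D[np.arange(X.shape[0]), labels] ** 2).sum())
    history.append(inertia)
    return ClusteringModel(k=k, centers=centers, seed=seed, inertia=inertia,
                           inertia_history=history, n_iter=n_iter)


def assign(model: ClusteringModel, reduced) -> np.ndarray | list[np.ndarray]:
    """Nearest-center microstate label per frame (Euclidean; ties -> lowest index).

    Accepts one (frames, m) array or a list of them; returns matching shape.
    """
    single = not isinstance(reduced, (list, tuple))
    trajs = [reduced] if single else list(reduced)
    out = []
    for t in trajs:
        X = np.atleast_2d(np.asarray(t, dtype=float))
        if X.shape[1] != model.centers.shape[1]:
            raise ValueError(
                f"data dimension {X.shape[1]} does not match model "
                f"dimension {model.centers.shape[1]}"
            )
        labels = np.empty(X.shape[0], dtype=np.int64)
        for a in range(0, X.shape[0], 65536):  # chunked: bounded memory
            b = min(a + 65536, X.shape[0])
            labels[a:b] = np.argmin(cdist(X[a:b], model.centers), axis=1)
        out.append(labels)
    return out[0] if single else out
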