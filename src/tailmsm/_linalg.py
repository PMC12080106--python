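"""Shared regularized linear algebra for covariance-based estimators."""

from __future__ import annotations

import numpy as np


def regularized_eigh(C: np.ndarray, epsilon: float = 1e-10, floor: float = 0.0):
    """Eigendecomposition of a symmetric PSD matrix, truncated to the
    numerically significant subspace (eigenvalues >= epsilon * largest and
    >= ``floor``).

    ``floor`` guards against directions whose variance is pure round-off:
    covariances of (near-)constant columns carry residues of order machine
    epsilon times the squared data magnitude, which a purely relative
    cutoff would keep.  Callers pass a floor proportional to the data's
    second moment.
    """
    C = 0.5 * (C + C.T)
    w, U = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    cutoff = max(epsilon * max(w[0], 0.0), floor, 0.0)
    keep = w > cutoff
    return w[keep], U[:, keep]


def regularized_inverse_sqrt(C: np.ndarray, epsilon: float = 1e-10,
                             floor: float = 0.0) -> np.ndarray:
    """C^{-1/2} restricted to the significant subspace: (d, r) whitening map."""
    w, U = regularized_eigh(C, epsilon, floor)
    return U / np.sqrt(w)


def roundoff_floor(X: np.ndarray) -> float:
    """Absolute eigenvalue floor for covariances computed from data X."""
    second_moment = float(np.max(np.mean(X * X, axis=0))) if X.size else 0.0
    return 1e-12 * max(second_moment, 1e-300)
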