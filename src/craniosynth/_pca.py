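"""Shared weighted-PCA core used by both the 3-D shape model and the
image PCA (the latter with uniform weights).

Given a data matrix X (K samples x p features) and positive feature weights
w, the weighted PCA diagonalizes the weighted sample covariance
C = Xc^T W Xc / (K-1). It is computed through the thin SVD of the
weight-scaled centered data, so components V satisfy V^T W V = I
(orthonormal under the weighted inner product) and eigenvalues are the
squared singular values / (K-1). With w = 1 this reduces to ordinary PCA.
"""

from __future__ import annotations

import numpy as np

#: eigenvalues below this fraction of the largest are treated as exactly zero
_RELATIVE_RANK_TOL = 1e-10


def weighted_pca(
    X: np.ndarray, weights: np.ndarray, variance_fraction: float = 0.95
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (mean, components, eigenvalues) truncated at the smallest
    number of components whose cumulative normalized variance reaches
    ``variance_fraction``.

    components: (p, q) with V^T diag(w) V = I; eigenvalues: (q,) descending.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a (K, p) data matrix with K >= 2")
    w = np.asarray(weights, dtype=float)
    if w.shape != (X.shape[1],) or np.any(w <= 0):
        raise ValueError("weights must be positive and match the feature count")
    if not (0 < variance_fraction <= 1):
        raise ValueError("variance_fraction must be in (0, 1]")

    mean = X.mean(axis=0)
    Xc = (X - mean) * np.sqrt(w)
    # thin SVD of the scaled data: eigenvalues of C are s^2/(K-1)
    _, s, vt = np.linalg.svd(Xc / np.sqrt(X.shape[0] - 1), full_matrices=False)
    eig = s**2
    # rank cutoff: relative to the spectrum and absolute relative to the data
    # magnitude (catches the all-identical case, where centering leaves only
    # rounding residue)
    floor = 1e-12 * float(np.mean((X * np.sqrt(w)) ** 2))
    if eig.size == 0 or eig[0] <= floor:
        return mean, np.empty((X.shape[1], 0)), np.empty(0)
    nonzero = eig > max(_RELATIVE_RANK_TOL * eig[0], floor)
    eig = eig[nonzero]
    vt = vt[nonzero]
    total = eig.sum()
    cum = np.cumsum(eig) / total
    q = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    q = min(q, len(eig))
    components = (vt[:q] / np.sqrt(w)).T  # undo the scaling: V^T W V = I
    return mean, components, eig[:q]


def pca_sample(
    mean: np.ndarray,
    components: np.ndarray,
    eigenvalues: np.ndarray,
    alphas: np.ndarray,
) -> np.ndarray:
    """Synthesize samples: x = mean + V Lambda^{1/2} alpha (rows of alphas)."""
    alphas = np.atleast_2d(np.asarray(alphas, dtype=float))
    q = components.shape[1]
    if alphas.shape[1] != q:
        raise ValueError(f"coefficient vectors must have length {q}, got {alphas.shape[1]}")
    return mean[None, :] + alphas * np.sqrt(eigenvalues) @ components.T
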