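"""Shared principal-component machinery for the shape, texture and combined models.

All three statistical models in an appearance model are plain PCAs that differ
only in what the rows of the data matrix are (aligned shape vectors, normalized
texture vectors, weighted concatenations of the two parameter sets).  This
module factors out the one eigendecomposition they share, together with the
conventions that make trained models reproducible:

* eigenvalues below ``rank_tol`` times the largest are treated as exactly zero
  (rank-deficient training sets are common: identical shapes, tiny samples);
* the retained mode count is the smallest one whose cumulative eigenvalue
  fraction reaches ``variance_retained``;
* each eigenvector's sign is fixed so its first nonzero component is positive,
  which makes serialized models byte-stable across BLAS builds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

RANK_TOL = 1e-12


@dataclass
class PCAResult:
    mean: np.ndarray          # (d,)
    components: np.ndarray    # (d, k), orthonormal columns
    eigenvalues: np.ndarray   # (k,), nonincreasing
    total_variance: float     # sum of *all* nonzero eigenvalues, not just kept


def fix_signs(components: np.ndarray, tol: float = RANK_TOL) -> np.ndarray:
    """Flip eigenvector signs so the first nonzero entry of each is positive."""
    out = components.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        nz = np.flatnonzero(np.abs(col) > tol)
        if nz.size and col[nz[0]] < 0:
            out[:, j] = -col
    return out


def fit_pca(X: np.ndarray, variance_retained: float, *, center: bool = True,
            max_components: int | None = None) -> PCAResult:
    """PCA of the rows of ``X`` keeping enough modes for ``variance_retained``.

    With ``center=False`` the data are assumed to have zero mean by
    construction (the combined model's parameter vectors are projections onto
    centered bases, so their sample means vanish identically).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("expected a 2-D data matrix (samples x features)")
    m = X.shape[0]
    if m < 2:
        raise ValueError("PCA requires at least 2 samples")
    if not 0.0 < variance_retained <= 1.0:
        raise ValueError("variance_retained must lie in (0, 1]")

    mean = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mean
    # SVD of the centered data: eigenvalues of the sample covariance are s^2/(m-1).
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = svals**2 / (m - 1)
    # rank cutoff: relative to the leading eigenvalue, but never below the
    # cancellation noise of subtracting the mean (~eps * |X|), which is what
    # survives when all samples are identical
    noise = 100.0 * (np.finfo(np.float64).eps * np.linalg.norm(X)) ** 2 / (m - 1)
    if eig.size:
        eig[eig < max(RANK_TOL * eig[0], noise)] = 0.0

    limit = m - 1 if center else min(m, X.shape[1])
    if max_components is not None:
        limit = min(limit, max_components)
    nonzero = int(np.count_nonzero(eig[:limit]))

    total = float(eig[:nonzero].sum())
    if total == 0.0 or nonzero == 0:
        k = 0
    elif variance_retained >= 1.0:
        k = nonzero
    else:
        frac = np.cumsum(eig[:nonzero]) / total
        k = int(np.searchsorted(frac, variance_retained - 1e-15) + 1)
        k = min(k, nonzero)

    components = fix_signs(Vt[:k].T) if k else np.zeros((X.shape[1], 0))
    return PCAResult(mean=mean, components=components,
                     eigenvalues=eig[:k].copy(), total_variance=total)
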