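"""Unit-variance scaling and principal component analysis of feature profiles.

The PCA is the plain centered-SVD decomposition: columns (features) are
mean-centered, the centered matrix is factored as ``U S Vt``, scores are the
projections onto the right singular vectors and variance explained per
component is ``s_i^2 / sum s^2``.  A fixed sign convention (the
largest-magnitude entry of each loading column is made positive) removes the
SVD sign ambiguity so outputs are reproducible.

Group score clouds are summarised by 95% confidence ellipses of the 2-D
covariance: semi-axes ``sqrt(chi2_2(level) * eigenvalue)`` along the
covariance eigenvectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats

__all__ = ["PCAResult", "Ellipse", "unit_variance_scale", "pca_svd", "confidence_ellipse"]


def _as_matrix(matrix) -> Tuple[np.ndarray, object, object]:
    """Accept a DataFrame or ndarray; return (values, index, columns)."""
    try:  # pandas without importing it at module scope for typing only
        index = matrix.index
        columns = matrix.columns
        values = matrix.to_numpy(dtype=float)
    except AttributeError:
        values = np.asarray(matrix, dtype=float)
        index = columns = None
    return values, index, columns


def unit_variance_scale(matrix) -> Tuple[np.ndarray, np.ndarray]:
    """Scale each feature column to unit sample variance (ddof=1).

    Returns ``(scaled, zero_variance)`` where ``zero_variance`` flags constant
    columns, which are set to all-zero rather than divided by zero.  The mean
    is not removed here (centering happens inside the PCA).
    """
    values, _, _ = _as_matrix(matrix)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("unit-variance scaling needs a 2-D matrix with >= 2 samples")
    std = values.std(axis=0, ddof=1)
    zero_variance = std == 0.0
    scaled = np.zeros_like(values)
    nz = ~zero_variance
    scaled[:, nz] = values[:, nz] / std[nz]
    return scaled, zero_variance


@dataclass(frozen=True)
class PCAResult:
    """Scores (samples x k), loadings (features x k, orthonormal columns),
    variance_explained (fraction of total variance per component)."""

    scores: np.ndarray
    loadings: np.ndarray
    variance_explained: np.ndarray
    n_components: int


def pca_svd(matrix, n_components: int) -> PCAResult:
    """Mean-center columns and decompose by SVD.

    ``n_components`` must satisfy ``1 <= k <= min(n_samples - 1, n_features)``
    (at most ``n - 1`` non-trivial components exist after centering).
    """
    values, _, _ = _as_matrix(matrix)
    if values.ndim != 2:
        raise ValueError("expected a 2-D samples x features matrix")
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix contains non-finite entries")
    n, p = values.shape
    max_k = min(n - 1, p)
    if not (1 <= n_components <= max_k):
        raise ValueError(f"n_components must be in [1, {max_k}], got {n_components}")
    centered = values - values.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = float(np.sum(s**2))
    loadings = vt[:n_components].T.copy()  # features x k
    # sign convention: largest-|entry| of each loading column positive
    for j in range(n_components):
        col = loadings[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            loadings[:, j] = -col
    scores = centered @ loadings
    if total == 0.0:
        variance_explained = np.zeros(n_components)
    else:
        variance_explained = (s[:n_components] ** 2) / total
    return PCAResult(scores=scores, loadings=loadings,
                     variance_explained=variance_explained, n_components=n_components)


@dataclass(frozen=True)
class Ellipse:
    """A confidence ellipse: center, semi-axis lengths (major first),
    orientation of the major axis in radians, and a degeneracy flag."""

    center: Tuple[float, float]
    semi_axes: Tuple[float, float]
    angle_rad: float
    degenerate: bool = False


def confidence_ellipse(points, level: float = 0.95) -> Ellipse:
    """Covariance (data) confidence ellipse of a 2-D point cloud.

    Semi-axes are ``sqrt(chi2_2(level) * eigenvalues)`` of the sample
    covariance; for an isotropic unit-variance cloud at the 95% level the
    radius is ``sqrt(5.991)``.  Requires >= 3 points; a singular covariance
    yields a degenerate (line or point) ellipse with the flag set.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an n x 2 array of scores")
    if pts.shape[0] < 3:
        raise ValueError("confidence ellipse needs at least 3 points")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]  # major axis first
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    q = stats.chi2.ppf(level, df=2)
    semi_axes = np.sqrt(q * eigvals)
    angle = float(np.arctan2(eigvecs[1, 0], eigvecs[0, 0]))
    degenerate = bool(eigvals[-1] <= 1e-12 * max(eigvals[0], 1.0))
    return Ellipse(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(semi_axes[0]), float(semi_axes[1])),
        angle_rad=angle,
        degenerate=degenerate,
    )
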