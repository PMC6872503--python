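"""Functional principal component summaries of regions and genes.

Two flavours are provided:

* ``fpca_region`` — the subjects x voxels intensity matrix of one region of
  interest is centered (optionally pre-smoothed on the voxel grid) and
  decomposed by SVD; the leading left singular vectors scaled by their
  singular values are the per-subject FPC scores.

* ``fpca_gene`` — each subject's genotype profile over the SNPs of one gene,
  viewed as a function of genomic position rescaled to [0, 1], is expanded in
  a B-spline basis; the eigendecomposition of the (Gram-weighted) coefficient
  covariance yields classical 1D functional principal component scores.

Scores are centered, mutually orthogonal, and deterministic: the sign of each
component is fixed by making its largest-magnitude loading positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import BSpline

from .synthetic import ValidationError


@dataclass
class FPCScores:
    """Per-subject scores plus the spectrum of the decomposition."""

    scores: np.ndarray                 # (n_subjects, k)
    eigenvalues: np.ndarray            # full non-increasing spectrum
    explained_variance_ratio: np.ndarray
    basis: str
    loadings: np.ndarray | None = None  # (features, k) in the fitted basis
    meta: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def _pick_k(eigenvalues, n_components, variance_target, max_components):
    if n_components is not None:
        return int(n_components)
    total = eigenvalues.sum()
    if total <= 0:
        return 1
    frac = np.cumsum(eigenvalues) / total
    k = int(np.searchsorted(frac, variance_target) + 1)
    return min(k, max_components, len(eigenvalues))


def _fix_signs(scores, loadings):
    """Largest-|loading| entry of each component made positive."""
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
            scores[:, j] = -scores[:, j]
    return scores, loadings


def _svd_scores(X_centered, n_components, variance_target, max_components,
                basis, meta):
    n = X_centered.shape[0]
    U, S, Vt = np.linalg.svd(X_centered, full_matrices=False)
    eigenvalues = S ** 2 / max(n - 1, 1)
    ratio = eigenvalues / eigenvalues.sum() if eigenvalues.sum() > 0 else eigenvalues
    k = _pick_k(eigenvalues, n_components, variance_target, max_components)
    if k > min(n - 1, X_centered.shape[1]):
        raise ValidationError(
            f"n_components={k} exceeds min(n_subjects-1, n_features)="
            f"{min(n - 1, X_centered.shape[1])}")
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T.copy()
    scores, loadings = _fix_signs(scores, loadings)
    return FPCScores(scores=scores, eigenvalues=eigenvalues,
                     explained_variance_ratio=ratio, basis=basis,
                     loadings=loadings, meta=meta)


def fpca_region(matrix, n_components: int | None = None,
                variance_target: float = 0.8, max_components: int = 5,
                voxel_coords=None, smooth_sigma: float = 0.0) -> FPCScores:
    """FPC scores of a subjects x voxels region matrix.

    If ``voxel_coords`` (m, 3) and ``smooth_sigma > 0`` are given, each
    subject's region image is Gaussian-smoothed inside the region's bounding
    box (mask-normalized so edge voxels are not biased) before decomposition.
    """
    X = np.asarray(matrix, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValidationError("matrix must be (n_subjects >= 2, n_voxels >= 1)")
    if not np.all(np.isfinite(X)):
        raise ValidationError("matrix contains non-finite values")
    if smooth_sigma > 0 and voxel_coords is not None:
        X = _smooth_region(X, np.asarray(voxel_coords, dtype=int), smooth_sigma)
    Xc = X - X.mean(axis=0)
    return _svd_scores(Xc, n_components, variance_target, max_components,
                       basis="voxel", meta={"smooth_sigma": smooth_sigma})


def _smooth_region(X, coords, sigma):
    offset = coords.min(axis=0)
    local = coords - offset
    shape = tuple(local.max(axis=0) + 1)
    mask = np.zeros(shape)
    mask[tuple(local.T)] = 1.0
    norm = ndimage.gaussian_filter(mask, sigma)
    out = np.empty_like(X)
    for i, row in enumerate(X):
        img = np.zeros(shape)
        img[tuple(local.T)] = row
        sm = ndimage.gaussian_filter(img, sigma)
        out[i] = (sm / np.where(norm > 0, norm, 1.0))[tuple(local.T)]
    return out


def _bspline_design(s: np.ndarray, n_basis: int):
    """B-spline design matrix over [0, 1] with ``n_basis`` functions."""
    degree = min(3, n_basis - 1)
    n_interior = n_basis - degree - 1
    interior = np.linspace(0, 1, n_interior + 2)[1:-1]
    t = np.r_[np.zeros(degree + 1), interior, np.ones(degree + 1)]
    s = np.clip(s, 0.0, 1.0 - 1e-12)  # right-open support at the last knot
    B = BSpline.design_matrix(s, t, degree).toarray()
    grid = np.linspace(0, 1 - 1e-12, 501)
    Bg = BSpline.design_matrix(grid, t, degree).toarray()
    gram = np.trapezoid(Bg[:, :, None] * Bg[:, None, :], grid, axis=0)
    return B, gram


def fpca_gene(genotypes, positions, n_components: int | None = None,
              variance_target: float = 0.8, max_components: int = 5,
              max_basis: int = 10) -> FPCScores:
    """Classical 1D FPC scores of a subjects x SNPs genotype matrix.

    SNP positions are rescaled to [0, 1]; profiles are expanded in a B-spline
    basis (at most ``max_basis`` functions), and the Gram-weighted coefficient
    covariance is decomposed.  Genes with a single SNP bypass the expansion
    and return the centered genotype as the sole score.
    """
    X = np.asarray(genotypes, dtype=np.float64)
    pos = np.asarray(positions, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("genotypes must be (n_subjects >= 2, n_snps)")
    if X.shape[1] != pos.size:
        raise ValidationError("positions length must match the SNP count")
    if np.any(np.diff(pos) <= 0) and pos.size > 1:
        raise ValidationError("SNP positions must be strictly increasing")
    if np.all(np.ptp(X, axis=0) == 0):
        raise ValidationError("monomorphic gene: no genotype variation")

    if X.shape[1] == 1:
        score = (X - X.mean(axis=0))
        var = np.array([score.var(ddof=1)])
        return FPCScores(scores=score, eigenvalues=var,
                         explained_variance_ratio=np.array([1.0]),
                         basis="single-snp", loadings=np.ones((1, 1)))

    s = (pos - pos.min()) / (pos.max() - pos.min())
    n_basis = min(X.shape[1], max_basis)
    B, gram = _bspline_design(s, n_basis)
    # least-squares basis coefficients per subject
    coef, *_ = np.linalg.lstsq(B, X.T, rcond=None)
    C = coef.T  # (n_subjects, n_basis)
    w, V = np.linalg.eigh(gram)
    half = V @ np.diag(np.sqrt(np.clip(w, 0, None))) @ V.T
    Cc = (C - C.mean(axis=0)) @ half
    return _svd_scores(Cc, n_components, variance_target, max_components,
                       basis=f"bspline({n_basis})",
                       meta={"n_basis": n_basis, "positions": pos})
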