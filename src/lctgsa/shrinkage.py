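"""Sample and shrinkage covariance estimation for small-sample expression data.

When a gene set is larger than the sample size (p > n) the sample covariance
matrix of the set's expression values is singular, so any statistic that needs
its inverse is undefined.  The remedy used here is correlation shrinkage in the
style of Schäfer & Strimmer: sample variances are kept exactly, while every
off-diagonal correlation is multiplied by ``1 - lambda*``, with the intensity
``lambda*`` estimated from the data as

    lambda* = sum_{h != h'} Var(r_hh') / sum_{h != h'} r_hh'^2

where ``Var(r_hh')`` is the empirical variance of the per-sample standardized
cross-product terms.  The resulting matrix is well conditioned whenever
``lambda* > 0`` and all variances are positive.

The module also provides the orthogonal transform ``V = Xc @ U @ D^{-1/2}``
built from the eigendecomposition ``Omega* = U D U^T``; its columns are
uncorrelated with unit variance under ``Omega*``, which is the computational
trick that lets a permutation test reuse one eigendecomposition for every
permuted phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CenteredMatrix",
    "ShrinkageFit",
    "center_columns",
    "sample_covariance",
    "shrinkage_intensity",
    "shrink_covariance",
    "orthogonal_transform",
]

#: relative eigenvalue cutoff below which components are dropped from the
#: transform (D^{-1/2} must not amplify numerical noise)
EIGENVALUE_RTOL = 1e-10


@dataclass(frozen=True)
class CenteredMatrix:
    """A samples x genes matrix whose columns (genes) have zero mean.

    Attributes
    ----------
    values : ndarray, shape (n_samples, p_genes)
        Column-centered expression values.
    column_means : ndarray, shape (p_genes,)
        The per-gene means that were subtracted.
    """

    values: np.ndarray
    column_means: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def p_genes(self) -> int:
        return self.values.shape[1]


def center_columns(X, genes_in_rows: bool = True) -> CenteredMatrix:
    """Orient a matrix to samples x genes and remove each gene's mean.

    Parameters
    ----------
    X : array-like
        Expression values.  With ``genes_in_rows=True`` (the microarray file
        convention) the input is genes x samples and is transposed on ingest;
        otherwise it is taken as samples x genes.
    genes_in_rows : bool
        Orientation of the input.

    Returns
    -------
    CenteredMatrix
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-dimensional matrix")
    M = X.T if genes_in_rows else X
    if M.shape[0] < 2:
        raise ValueError("insufficient samples: need at least 2")
    means = M.mean(axis=0)
    return CenteredMatrix(values=M - means, column_means=means)


def sample_covariance(xc: CenteredMatrix) -> np.ndarray:
    """Unbiased (n-1 denominator) sample covariance of the genes, p x p."""
    n = xc.n_samples
    return xc.values.T @ xc.values / (n - 1)


def shrinkage_intensity(xc: CenteredMatrix) -> float:
    """Estimate the optimal correlation-shrinkage intensity ``lambda*``.

    Uses the empirical variance of the standardized cross-product terms:
    with z the (n-1)-denominator standardized data and w_hh'l = z_hl * z_h'l,

        Var(r_hh') = n / (n-1)^3 * sum_l (w_hh'l - mean_l w_hh'l)^2

    The returned intensity is clamped to [0, 1].  By convention, if every
    off-diagonal sample correlation is exactly zero (including p = 1) the
    intensity is 1: the covariance is already diagonal and full shrinkage
    leaves it unchanged.
    """
    n, p = xc.n_samples, xc.p_genes
    if n < 3:
        raise ValueError("insufficient samples: variance of a correlation needs at least 3")
    if p == 1:
        return 1.0
    sd = np.sqrt((xc.values**2).sum(axis=0) / (n - 1))
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"degenerate gene: zero variance at column {bad}")
    Z = xc.values / sd
    R = Z.T @ Z / (n - 1)
    denom = float((R**2).sum() - (np.diag(R) ** 2).sum())
    if denom <= 0.0:
        return 1.0
    W_bar = Z.T @ Z / n
    W2 = (Z**2).T @ (Z**2)  # sum_l w_hh'l^2
    var_mat = W2 - n * W_bar**2  # sum_l (w - w_bar)^2
    numer = n / (n - 1) ** 3 * float(var_mat.sum() - np.trace(var_mat))
    return float(np.clip(numer / denom, 0.0, 1.0))


@dataclass(frozen=True)
class ShrinkageFit:
    """Shrunk covariance ``Omega*`` with its eigendecomposition and transform.

    Attributes
    ----------
    lambda_star : float in [0, 1]
        Estimated (or supplied) shrinkage intensity.
    omega_star : ndarray, p x p
        Shrunk covariance: sample variances on the diagonal, off-diagonal
        entries ``r_hh' * (1 - lambda*) * sqrt(w_hh * w_h'h')``.
    eigvecs : ndarray, p x p
        Orthogonal eigenvector matrix U, columns ordered by descending
        eigenvalue.
    eigvals : ndarray, (p,)
        Non-negative eigenvalues D in descending order (tiny negatives from
        rounding are clipped to 0).
    transform : ndarray, p x k
        ``U[:, kept] @ diag(D_kept^{-1/2})`` over the k retained components
        (eigenvalues above ``EIGENVALUE_RTOL`` relative to the largest).
    """

    lambda_star: float
    omega_star: np.ndarray
    eigvecs: np.ndarray
    eigvals: np.ndarray
    transform: np.ndarray

    @property
    def n_components(self) -> int:
        return self.transform.shape[1]


def shrink_covariance(xc: CenteredMatrix, lambda_star: float | None = None) -> ShrinkageFit:
    """Compute the shrinkage covariance estimate and its eigendecomposition.

    Parameters
    ----------
    xc : CenteredMatrix
    lambda_star : float, optional
        Override the estimated intensity (useful to force ``0`` = raw sample
        covariance or ``1`` = diagonal).  Estimated from the data when None.
    """
    n = xc.n_samples
    if n < 3:
        raise ValueError("insufficient samples: need at least 3")
    S = sample_covariance(xc)
    variances = np.diag(S).copy()
    if np.any(variances <= 0):
        bad = int(np.flatnonzero(variances <= 0)[0])
        raise ValueError(f"degenerate gene: zero variance at column {bad}")
    lam = shrinkage_intensity(xc) if lambda_star is None else float(lambda_star)
    factor = min(1.0, max(0.0, 1.0 - lam))
    omega = factor * S
    np.fill_diagonal(omega, variances)
    omega = (omega + omega.T) / 2.0
    w, U = np.linalg.eigh(omega)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    U = U[:, order]
    keep = w > EIGENVALUE_RTOL * w[0]
    transform = U[:, keep] / np.sqrt(w[keep])
    return ShrinkageFit(
        lambda_star=float(np.clip(lam, 0.0, 1.0)),
        omega_star=omega,
        eigvecs=U,
        eigvals=w,
        transform=transform,
    )


def orthogonal_transform(xc: CenteredMatrix, fit: ShrinkageFit) -> np.ndarray:
    """Project the centered data onto the whitening basis: ``V = Xc @ U D^{-1/2}``.

    The columns of V satisfy ``transform^T Omega* transform = I`` on the
    retained components, so the LCT statistic is a plain sum of squared
    phenotype--column covariances in this basis.
    """
    if fit.omega_star.shape[0] != xc.p_genes:
        raise ValueError("fit was computed for a different number of genes")
    return xc.values @ fit.transform
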