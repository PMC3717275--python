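"""Gene-set association statistics for a continuous phenotype, with a
permutation engine.

Four self-contained test statistics are provided.  All of them test the null
hypothesis that no linear combination of the set's (centered) expression
values X_1..X_p is associated with the phenotype Y, and all obtain p-values
by permuting the phenotype across samples, which preserves the gene--gene
correlation structure.

LCT
    The most-significant-linear-combination statistic.  Maximising the squared
    sample correlation of Y with ``Z(beta) = sum_h beta_h X_h`` over beta gives
    the quadratic form ``Cov(Y,X)^T Omega*^{-1} Cov(Y,X)`` in the shrunk
    covariance ``Omega*``.  In the whitened basis ``V = Xc U D^{-1/2}`` this is
    simply ``sum_j Cov(Y, V_j)^2``, so the eigendecomposition is computed once
    and reused for every permutation.
LCT2
    The squared L2 norm of the shrinkage regression-function estimate
    ``f = Xc ((n-1) Omega*)^{-1} Xc^T Yc``; reduces to the OLS fitted-value
    norm when the shrinkage intensity is 0 and Xc has full column rank.
SAMGS
    The continuous-phenotype SAM-GS statistic: the sum over genes of the
    squared Wald statistic (slope over its standard error) from the simple
    linear regression of Y on each gene.
GLOBAL
    The Global Test score statistic of the random-effects formulation,
    ``Q = Yc^T Xc Xc^T Yc / p``; positive scaling constants are irrelevant
    under permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .shrinkage import (
    CenteredMatrix,
    ShrinkageFit,
    center_columns,
    orthogonal_transform,
    shrink_covariance,
)

__all__ = [
    "METHODS",
    "Phenotype",
    "TestResult",
    "GeneSetData",
    "lct_statistic",
    "lct2_statistic",
    "samgs_statistic",
    "globaltest_statistic",
    "permutation_indices",
    "permutation_pvalue",
    "test_gene_set",
]

METHODS = ("LCT", "LCT2", "SAMGS", "GLOBAL")

# Relative tolerance below which the per-gene regression residual sum of
# squares is treated as zero (gene collinear with the phenotype).
_COLLINEAR_RTOL = 1e-12


class Phenotype:
    """A continuous phenotype: raw values plus their centered version."""

    __slots__ = ("values", "centered")

    def __init__(self, values):
        v = np.asarray(values, dtype=float).ravel()
        if v.size < 2:
            raise ValueError("phenotype needs at least 2 values")
        self.values = v
        self.centered = v - v.mean()

    def __len__(self) -> int:
        return self.values.size


def _centered_phenotype(y, n_expected: int | None = None) -> np.ndarray:
    yc = y.centered if isinstance(y, Phenotype) else Phenotype(y).centered
    if n_expected is not None and yc.size != n_expected:
        raise ValueError(f"phenotype length {yc.size} does not match sample count {n_expected}")
    return yc


@dataclass(frozen=True)
class TestResult:
    """Outcome of one permutation test of one gene set."""

    statistic: float
    p_value: float
    n_permutations: int
    method: str
    seed: int | None = None


def lct_statistic(y, V: np.ndarray) -> float:
    """LCT statistic: sum of squared sample covariances of Y with the columns
    of the whitened matrix V (proportionality constants dropped)."""
    V = np.asarray(V, dtype=float)
    n = V.shape[0]
    yc = _centered_phenotype(y, n)
    c = yc @ V / (n - 1)
    return float(c @ c)


def lct2_statistic(y, xc: CenteredMatrix, fit: ShrinkageFit) -> float:
    """LCT2 statistic: squared L2 norm of the shrinkage regression function.

    ``f = Xc ((n-1) Omega*)^{-1} Xc^T Yc`` with the inverse applied through
    the stored eigendecomposition (a pseudo-inverse over retained components).
    """
    n = xc.n_samples
    yc = _centered_phenotype(y, n)
    T = fit.transform
    f = xc.values @ (T @ (T.T @ (xc.values.T @ yc))) / (n - 1)
    return float(f @ f)


def samgs_statistic(y, xc: CenteredMatrix) -> float:
    """Continuous SAM-GS: sum over genes of the squared Wald statistic of the
    slope in the per-gene simple linear regression of Y on the gene."""
    n = xc.n_samples
    if n < 4:
        raise ValueError("insufficient samples: per-gene regression needs at least 4")
    yc = _centered_phenotype(y, n)
    syy = float(yc @ yc)
    if syy == 0.0:
        return 0.0
    sxy = xc.values.T @ yc
    sxx = (xc.values**2).sum(axis=0)
    denom = sxx * syy - sxy**2
    bad = denom <= _COLLINEAR_RTOL * sxx * syy
    if np.any(bad):
        g = int(np.flatnonzero(bad)[0])
        raise ValueError(f"degenerate regression: gene column {g} is collinear with the phenotype")
    return float(((n - 2) * sxy**2 / denom).sum())


def globaltest_statistic(y, xc: CenteredMatrix) -> float:
    """Global Test score statistic ``Q = Yc^T Xc Xc^T Yc / p``."""
    n, p = xc.n_samples, xc.p_genes
    if n < 3:
        raise ValueError("insufficient samples: need at least 3")
    yc = _centered_phenotype(y, n)
    s = xc.values.T @ yc
    return float(s @ s) / p


class GeneSetData:
    """Per-set quantities computed once and shared by all permutations.

    Holds the centered matrix, the shrinkage fit, the whitened matrix V, and
    the cached Gram pieces used by the vectorised statistic evaluations.

    Parameters
    ----------
    X : array-like, samples x genes (or genes x samples with
        ``samples_in_rows=False``)
    lambda_star : float, optional
        Forwarded to :func:`lctgsa.shrinkage.shrink_covariance`.
    """

    def __init__(self, X, samples_in_rows: bool = True, lambda_star: float | None = None):
        self.xc = center_columns(X, genes_in_rows=not samples_in_rows)
        self.fit = shrink_covariance(self.xc, lambda_star=lambda_star)
        self.V = orthogonal_transform(self.xc, self.fit)
        self._gram_V = self.V.T @ self.V
        self._sxx = (self.xc.values**2).sum(axis=0)

    @property
    def n_samples(self) -> int:
        return self.xc.n_samples

    @property
    def p_genes(self) -> int:
        return self.xc.p_genes

    def statistic(self, y, method: str) -> float:
        """Evaluate one named statistic for one phenotype vector."""
        if method == "LCT":
            return lct_statistic(y, self.V)
        if method == "LCT2":
            return lct2_statistic(y, self.xc, self.fit)
        if method == "SAMGS":
            return samgs_statistic(y, self.xc)
        if method == "GLOBAL":
            return globaltest_statistic(y, self.xc)
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")

    def batch_statistics(self, Yc: np.ndarray, methods: Sequence[str]) -> dict[str, np.ndarray]:
        """Evaluate statistics for many centered phenotype rows at once.

        Parameters
        ----------
        Yc : ndarray, (m, n)
            Each row a centered phenotype vector (permutations of a centered
            vector stay centered).
        methods : sequence of method names

        Returns
        -------
        dict mapping method name to a length-m array of statistic values.
        """
        n = self.n_samples
        out: dict[str, np.ndarray] = {}
        A = None
        S = None
        for method in methods:
            if method in ("LCT", "LCT2"):
                if A is None:
                    A = Yc @ self.V
                if method == "LCT":
                    out[method] = (A * A).sum(axis=1) / (n - 1) ** 2
                else:
                    out[method] = ((A @ self._gram_V) * A).sum(axis=1) / (n - 1) ** 2
            elif method in ("SAMGS", "GLOBAL"):
                if S is None:
                    S = Yc @ self.xc.values
                if method == "GLOBAL":
                    out[method] = (S * S).sum(axis=1) / self.p_genes
                else:
                    if n < 4:
                        raise ValueError("insufficient samples: per-gene regression needs at least 4")
                    syy = (Yc * Yc).sum(axis=1)
                    with np.errstate(invalid="ignore", divide="ignore"):
                        denom = self._sxx[None, :] * syy[:, None] - S * S
                        t2 = (n - 2) * S * S / denom
                    degenerate = denom <= _COLLINEAR_RTOL * self._sxx[None, :] * syy[:, None]
                    if np.any(degenerate & (syy[:, None] > 0)):
                        raise ValueError("degenerate regression: a gene is collinear with a phenotype row")
                    t2 = np.where(syy[:, None] == 0, 0.0, t2)
                    out[method] = t2.sum(axis=1)
            else:
                raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
        return out


def permutation_indices(n: int, B: int, seed) -> np.ndarray:
    """A B x n matrix of seeded sample permutations (rows independent).

    ``seed`` may be an int, a SeedSequence, or a Generator; permutations are
    drawn uniformly without enforcing distinctness.
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.permuted(np.tile(np.arange(n), (B, 1)), axis=1)


def permutation_pvalue(
    stat: Callable[[Phenotype], float],
    Y,
    B: int,
    seed,
    method: str = "custom",
) -> TestResult:
    """Permutation p-value of an arbitrary statistic of the phenotype.

    The statistic callable receives a :class:`Phenotype` (the gene-side data
    being closed over) and must be deterministic.  The p-value uses the
    add-one convention ``(1 + #{perm >= observed}) / (B + 1)``, with ties
    counted toward the numerator.
    """
    y = Y if isinstance(Y, Phenotype) else Phenotype(Y)
    if B < 1:
        raise ValueError("need at least one permutation")
    observed = stat(y)
    idx = permutation_indices(len(y), B, seed)
    exceed = 0
    for row in idx:
        if stat(Phenotype(y.values[row])) >= observed:
            exceed += 1
    p = (1 + exceed) / (B + 1)
    return TestResult(
        statistic=float(observed),
        p_value=p,
        n_permutations=B,
        method=method,
        seed=seed if isinstance(seed, int) else None,
    )


def test_gene_set(
    X=None,
    Y=None,
    methods: Sequence[str] = METHODS,
    B: int = 1000,
    seed: int | None = 0,
    perm_indices: np.ndarray | None = None,
    data: GeneSetData | None = None,
) -> dict[str, TestResult]:
    """Permutation tests of one gene set with one shared permutation matrix.

    Either ``X`` (samples x genes) or a precomputed :class:`GeneSetData` must
    be given.  All requested methods are evaluated on the same seeded
    permutations so that method comparisons are not confounded by permutation
    noise; the gene-side eigendecomposition is computed once.
    """
    if data is None:
        if X is None:
            raise ValueError("provide either X or data")
        data = GeneSetData(X)
    y = Y if isinstance(Y, Phenotype) else Phenotype(Y)
    yc = _centered_phenotype(y, data.n_samples)
    if perm_indices is None:
        if B < 1:
            raise ValueError("need at least one permutation")
        perm_indices = permutation_indices(len(y), B, seed)
    B = perm_indices.shape[0]
    observed = data.batch_statistics(yc[None, :], methods)
    permuted = data.batch_statistics(yc[perm_indices], methods)
    results: dict[str, TestResult] = {}
    for m in methods:
        obs = float(observed[m][0])
        exceed = int((permuted[m] >= obs).sum())
        results[m] = TestResult(
            statistic=obs,
            p_value=(1 + exceed) / (B + 1),
            n_permutations=B,
            method=m,
            seed=seed,
        )
    return results
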