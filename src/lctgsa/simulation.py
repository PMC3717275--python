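"""Null and alternative simulation models for sizing and powering the tests.

The generative model: each replicate draws an n x p expression matrix X whose
rows are i.i.d. multivariate normal with mean 0 and a block correlation
structure (unit variances, so correlation = covariance):

* genes 1..p1 — compound symmetry, constant pairwise correlation rho;
* genes p1+1..p1+p2 — AR(1), correlation rho^|i-j| by index distance;
* remaining genes — independent.

The phenotype is ``Y ~ N(X mu, I)``.  Under the null mu = 0.  Under the
alternative, five of the first 20 components of mu are drawn from
``N(nu, |nu|)`` and five of the next 20 from ``N(-nu, |nu|)`` (|nu| read as a
variance), the rest 0; mu is re-drawn for every replicate dataset.

Experiments evaluate the permutation tests once per replicate, recording the
proportion of p-values at or below each nominal level — the empirical type-I
error when nu = 0, the empirical power otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import toeplitz

from .gsa_tests import METHODS, GeneSetData, Phenotype, permutation_indices, test_gene_set

__all__ = [
    "SimulationScenario",
    "SimulationSummary",
    "build_correlation_matrix",
    "draw_mu",
    "simulate_dataset",
    "run_type1_experiment",
    "run_power_curve",
]


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of the simulation grid.

    nu is the effect-scale parameter (0 = null model); nominal_levels are the
    significance levels at which rejections are tallied.
    """

    n: int
    p: int
    p1: int
    p2: int
    rho: float
    nu: float = 0.0
    n_replicates: int = 1000
    n_permutations: int = 1000
    nominal_levels: tuple[float, ...] = (0.005, 0.01, 0.05)
    seed: int = 0

    def __post_init__(self):
        if self.n < 2 or self.p < 1:
            raise ValueError("need n >= 2 and p >= 1")
        if self.p1 < 0 or self.p2 < 0 or self.p1 + self.p2 > self.p:
            raise ValueError("need p1 >= 0, p2 >= 0 and p1 + p2 <= p")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.nu < 0:
            raise ValueError("nu must be >= 0")
        if self.n_replicates < 1 or self.n_permutations < 1:
            raise ValueError("need at least one replicate and one permutation")
        if not all(0.0 < a < 1.0 for a in self.nominal_levels):
            raise ValueError("nominal levels must lie in (0, 1)")


@dataclass(frozen=True)
class SimulationSummary:
    """Per-method, per-level rejection proportions for one scenario."""

    scenario: SimulationScenario
    n_replicates: int
    rejection_rates: pd.DataFrame  # index: nominal level, columns: methods

    def rate(self, method: str, level: float) -> float:
        return float(self.rejection_rates.loc[level, method])

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-(method, level) frame, for TSV export."""
        df = self.rejection_rates.copy()
        df.index.name = "level"
        long = df.reset_index().melt(id_vars="level", var_name="method", value_name="rejection_rate")
        for name in ("n", "p", "p1", "p2", "rho", "nu"):
            long[name] = getattr(self.scenario, name)
        long["n_replicates"] = self.n_replicates
        long["n_permutations"] = self.scenario.n_permutations
        cols = ["n", "p", "p1", "p2", "rho", "nu", "method", "level", "rejection_rate", "n_replicates", "n_permutations"]
        return long[cols]


def build_correlation_matrix(p: int, p1: int, p2: int, rho: float) -> np.ndarray:
    """Block correlation matrix: compound symmetry (p1), AR(1) (p2), identity."""
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    if p1 < 0 or p2 < 0 or p1 + p2 > p:
        raise ValueError("need p1 >= 0, p2 >= 0 and p1 + p2 <= p")
    C = np.eye(p)
    if p1 > 0:
        C[:p1, :p1] = rho
        np.fill_diagonal(C[:p1, :p1], 1.0)
    if p2 > 0:
        ar = toeplitz(rho ** np.arange(p2))
        C[p1 : p1 + p2, p1 : p1 + p2] = ar
    return C


def draw_mu(p: int, nu: float, seed) -> np.ndarray:
    """Draw the sparse effect vector mu.

    Exactly five positions among the first 20 receive ``N(nu, |nu|)`` draws and
    five among positions 21-40 receive ``N(-nu, |nu|)`` (|nu| is a variance);
    everything else is 0.  ``nu = 0`` returns the zero vector (the null model).
    """
    if nu < 0:
        raise ValueError("nu must be >= 0")
    mu = np.zeros(p)
    if nu == 0:
        return mu
    if p < 40:
        raise ValueError("need p >= 40 to place effects in the first two 20-gene blocks")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = math.sqrt(abs(nu))
    pos = rng.choice(20, size=5, replace=False)
    mu[pos] = rng.normal(nu, sd, size=5)
    neg = 20 + rng.choice(20, size=5, replace=False)
    mu[neg] = rng.normal(-nu, sd, size=5)
    return mu


def _replicate_rng(sc: SimulationScenario, stream: int, replicate: int) -> np.random.Generator:
    # Independent, reproducible streams per (scenario seed, purpose, replicate).
    return np.random.default_rng(np.random.SeedSequence((sc.seed, stream, replicate)))


def simulate_dataset(
    sc: SimulationScenario,
    replicate_seed: int,
    _chol: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one (X, Y) replicate; deterministic given (scenario seed, replicate_seed)."""
    rng = _replicate_rng(sc, 0, replicate_seed)
    L = np.linalg.cholesky(build_correlation_matrix(sc.p, sc.p1, sc.p2, sc.rho)) if _chol is None else _chol
    X = rng.standard_normal((sc.n, sc.p)) @ L.T
    mu = draw_mu(sc.p, sc.nu, rng)
    Y = X @ mu + rng.standard_normal(sc.n)
    return X, Y


def _run_experiment(sc: SimulationScenario, methods: Sequence[str]) -> SimulationSummary:
    methods = tuple(methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; expected subset of {METHODS}")
    levels = np.asarray(sc.nominal_levels)
    chol = np.linalg.cholesky(build_correlation_matrix(sc.p, sc.p1, sc.p2, sc.rho))
    counts = {m: np.zeros(levels.size, dtype=int) for m in methods}
    for rep in range(sc.n_replicates):
        X, Y = simulate_dataset(sc, rep, _chol=chol)
        data = GeneSetData(X)
        idx = permutation_indices(sc.n, sc.n_permutations, _replicate_rng(sc, 1, rep))
        results = test_gene_set(Y=Phenotype(Y), methods=methods, perm_indices=idx, data=data)
        for m in methods:
            counts[m] += results[m].p_value <= levels
    rates = pd.DataFrame(
        {m: counts[m] / sc.n_replicates for m in methods},
        index=pd.Index(levels, name="level"),
    )
    return SimulationSummary(scenario=sc, n_replicates=sc.n_replicates, rejection_rates=rates)


def run_type1_experiment(sc: SimulationScenario, methods: Sequence[str] = METHODS) -> SimulationSummary:
    """Empirical type-I error of the permutation tests under the null (nu = 0)."""
    if sc.nu != 0:
        raise ValueError("type-I experiment requires nu = 0")
    return _run_experiment(sc, methods)


def run_power_curve(
    sc_template: SimulationScenario,
    nu_grid: Sequence[float],
    methods: Sequence[str] = METHODS,
) -> list[SimulationSummary]:
    """Empirical power along an ascending grid of effect scales nu.

    Each grid point reuses the template scenario with its nu replaced; the
    nu = 0 entry (if present) reproduces the type-I error.
    """
    nu_grid = list(nu_grid)
    if any(b < a for a, b in zip(nu_grid, nu_grid[1:])):
        raise ValueError("nu_grid must be sorted ascending")
    return [_run_experiment(replace(sc_template, nu=float(nu)), methods) for nu in nu_grid]
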