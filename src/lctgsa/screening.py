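"""Catalog-wide screening of gene sets against a continuous phenotype.

The pipeline mirrors common practice for expression studies: gene rows are
centered and scaled across samples, sets are intersected with the measured
genes and restricted to a size window (default 15-500 analyzed genes), every
retained set is tested with one shared seeded permutation matrix so that
p-values are comparable across sets and methods, and Storey q-values are
appended per method for multiplicity control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gsa_tests import METHODS, Phenotype, permutation_indices, test_gene_set

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "standardize_genes",
    "filter_sets",
    "screen",
    "storey_qvalues",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered collection of unique gene identifiers."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetCollection:
    """An ordered catalog of gene sets with unique names."""

    def __init__(self, sets: Iterable[GeneSet] = ()):
        self.sets = list(sets)
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise ValueError(f"duplicate gene set name {dup!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, key):
        if isinstance(key, str):
            for s in self.sets:
                if s.name == key:
                    return s
            raise KeyError(key)
        return self.sets[key]

    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def standardize_genes(X: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each gene row to mean 0, sd 1 (n-1 denominator).

    Zero-variance genes are dropped with a logged warning; if nothing
    survives, an error is raised.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    values = X.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("no usable genes: every gene has zero variance")
    if not keep.all():
        dropped = X.index[~keep]
        logger.warning("dropping %d zero-variance gene(s): %s%s", (~keep).sum(),
                       ", ".join(map(str, dropped[:5])), "..." if len(dropped) > 5 else "")
    values = values[keep]
    means = values.mean(axis=1, keepdims=True)
    out = (values - means) / values.std(axis=1, ddof=1, keepdims=True)
    return pd.DataFrame(out, index=X.index[keep], columns=X.columns)


def filter_sets(
    coll: GeneSetCollection,
    matrix_genes: Iterable[str],
    min_size: int = 15,
    max_size: int = 500,
) -> GeneSetCollection:
    """Intersect each set with the measured genes and keep sets whose analyzed
    (post-intersection) size lies in [min_size, max_size], inclusive."""
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    present = set(matrix_genes)
    kept = []
    for s in coll:
        genes = tuple(g for g in s.genes if g in present)
        if genes and min_size <= len(genes) <= max_size:
            kept.append(GeneSet(s.name, s.description, genes))
    return GeneSetCollection(kept)


def storey_qvalues(pvals, lam: float = 0.5, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with the fixed-lambda pi0 estimator.

    ``pi0 = min(1, #{p > lam} / ((1 - lam) m))``; q-values are the running
    minimum of ``pi0 * m * p_(j) / j`` over the sorted p-values, mapped back
    to the input order.  ``pi0`` may be overridden (pi0 = 1 gives
    Benjamini-Hochberg adjusted p-values).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = min(1.0, float((p > lam).sum()) / ((1.0 - lam) * m))
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def screen(
    X: pd.DataFrame,
    Y,
    coll: GeneSetCollection,
    methods: Sequence[str] = METHODS,
    B: int = 1000,
    seed: int = 0,
    min_size: int = 15,
    max_size: int = 500,
) -> pd.DataFrame:
    """Test every retained gene set against the phenotype.

    Parameters
    ----------
    X : DataFrame, genes x samples
        Raw expression values; standardized internally.
    Y : array-like, one value per sample (column order of X)
    coll : GeneSetCollection
    methods : which statistics to compute
    B : permutations (one shared seeded permutation matrix across all sets
        and methods)
    seed : permutation seed
    min_size, max_size : analyzed-size window for retained sets

    Returns
    -------
    DataFrame with columns ``set, size, analyzed_size`` then
    ``<method>_stat, <method>_p, <method>_q`` per method, one row per
    retained set in catalog order.
    """
    y = Y if isinstance(Y, Phenotype) else Phenotype(Y)
    if X.shape[1] != len(y):
        raise ValueError(f"expression has {X.shape[1]} samples but phenotype has {len(y)}")
    if B < 1:
        raise ValueError("need at least one permutation")
    methods = tuple(methods)
    Xs = standardize_genes(X)
    annotated = {s.name: len(s) for s in coll}
    retained = filter_sets(coll, Xs.index, min_size=min_size, max_size=max_size)
    columns = ["set", "size", "analyzed_size"]
    for m in methods:
        columns += [f"{m.lower()}_stat", f"{m.lower()}_p", f"{m.lower()}_q"]
    if len(retained) == 0:
        logger.warning("no gene sets retained after filtering")
        return pd.DataFrame(columns=columns)
    idx = permutation_indices(len(y), B, seed)
    logger.info("screening %d set(s), %d genes, %d samples, %d permutations",
                len(retained), Xs.shape[0], Xs.shape[1], B)
    rows = []
    for s in retained:
        sub = Xs.loc[list(s.genes)].to_numpy().T  # samples x genes
        res = test_gene_set(sub, y, methods=methods, perm_indices=idx, seed=seed)
        row = {"set": s.name, "size": annotated[s.name], "analyzed_size": len(s)}
        for m in methods:
            row[f"{m.lower()}_stat"] = res[m].statistic
            row[f"{m.lower()}_p"] = res[m].p_value
        rows.append(row)
    out = pd.DataFrame(rows)
    for m in methods:
        out[f"{m.lower()}_q"] = storey_qvalues(out[f"{m.lower()}_p"].to_numpy())
    return out[columns]
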