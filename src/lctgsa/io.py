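"""Readers and writers for the plain-text formats the pipeline touches.

Parsing is strict: the statistics assume complete numeric matrices, so any
non-numeric cell, ragged row or duplicate identifier is an immediate error
naming the offending location rather than a silent coercion.

Formats
-------
expression : TSV, genes x samples; first column gene IDs, header row sample IDs
phenotype  : 2-column TSV, sample ID then value (an optional header is
             detected by a non-numeric second field on the first line)
gene sets  : GMT — per line: set name, description, then member genes
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulation
from .screening import GeneSet, GeneSetCollection

__all__ = [
    "read_expression",
    "write_expression",
    "read_phenotype",
    "write_phenotype",
    "read_gmt",
    "write_gmt",
    "FixturePaths",
    "build_fixture_frames",
    "make_fixture",
]

logger = logging.getLogger(__name__)


def _parse_float(cell: str, where: str) -> float:
    try:
        v = float(cell)
    except ValueError:
        raise ValueError(f"non-numeric value {cell!r} {where}") from None
    if not math.isfinite(v):
        raise ValueError(f"non-finite value {cell!r} {where}")
    return v


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV into a DataFrame (genes as the index)."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].strip():
        raise ValueError(f"{path}: empty expression file")
    header = lines[0].split("\t")
    samples = header[1:]
    if not samples:
        raise ValueError(f"{path}: header has no sample identifiers")
    if len(set(samples)) != len(samples):
        raise ValueError(f"{path}: duplicate sample identifiers in header")
    ncol = len(header)
    genes: list[str] = []
    seen: set[str] = set()
    values: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != ncol:
            raise ValueError(f"{path}: ragged row at line {lineno}: expected {ncol} fields, got {len(parts)}")
        gene = parts[0]
        if gene in seen:
            raise ValueError(f"{path}: duplicate gene identifier {gene!r} at line {lineno}")
        seen.add(gene)
        genes.append(gene)
        values.append([
            _parse_float(cell, f"for gene {gene!r}, sample {samples[j]!r} (line {lineno})")
            for j, cell in enumerate(parts[1:])
        ])
    if not genes:
        raise ValueError(f"{path}: expression matrix has no genes")
    logger.info("read %d genes x %d samples from %s", len(genes), len(samples), path)
    return pd.DataFrame(np.asarray(values), index=genes, columns=samples)


def write_expression(X: pd.DataFrame, path) -> None:
    """Write a genes x samples DataFrame as the TSV dialect read back by
    :func:`read_expression` (values round-trip exactly via repr)."""
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(map(str, X.columns)) + "\n")
        for gene, row in zip(X.index, X.to_numpy()):
            fh.write(str(gene) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_phenotype(path) -> pd.Series:
    """Read a 2-column sample ID -> value TSV into a Series."""
    lines = Path(path).read_text().splitlines()
    ids: list[str] = []
    vals: list[float] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated fields, got {len(parts)}")
        if lineno == 1:
            try:
                float(parts[1])
            except ValueError:
                continue  # header line
        ids.append(parts[0])
        vals.append(_parse_float(parts[1], f"for sample {parts[0]!r} (line {lineno})"))
    if not ids:
        raise ValueError(f"{path}: empty phenotype file")
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sample identifiers")
    return pd.Series(vals, index=ids, name="phenotype")


def write_phenotype(y: pd.Series, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tphenotype\n")
        for sid, v in y.items():
            fh.write(f"{sid}\t{repr(float(v))}\n")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT catalog; duplicate genes within a set are dropped with a
    warning, duplicate set names and short lines are errors."""
    sets: list[GeneSet] = []
    names: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: line {lineno}: expected at least 3 tab-separated fields "
                             f"(name, description, genes), got {len(parts)}")
        name, description = parts[0], parts[1]
        if name in names:
            raise ValueError(f"{path}: line {lineno}: duplicate gene set name {name!r}")
        names.add(name)
        genes: list[str] = []
        seen: set[str] = set()
        for g in parts[2:]:
            if g in seen:
                logger.warning("%s: line %d: duplicate gene %r in set %r dropped", path, lineno, g, name)
                continue
            seen.add(g)
            genes.append(g)
        sets.append(GeneSet(name, description, tuple(genes)))
    return GeneSetCollection(sets)


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in coll:
            fh.write("\t".join((s.name, s.description) + s.genes) + "\n")


@dataclass(frozen=True)
class FixturePaths:
    """Paths of a generated expression/phenotype/catalog trio."""

    expression: Path
    phenotype: Path
    gmt: Path
    signal_set: str | None


def build_fixture_frames(
    n: int = 30,
    n_sets: int = 20,
    set_size: int = 40,
    p1: int = 10,
    p2: int = 10,
    rho: float = 0.3,
    nu: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, GeneSetCollection, str | None]:
    """In-memory synthetic screening dataset with the simulation study's
    statistical structure.

    Each set gets its own independent block of ``set_size`` genes drawn as
    MVN(0, block correlation(p1, p2, rho)).  With ``nu > 0`` the FIRST set is
    the planted signal set: the phenotype is ``N(X_set0 @ mu, I)`` with mu
    drawn by :func:`lctgsa.simulation.draw_mu` (requires ``set_size >= 40``);
    otherwise the phenotype is standard normal noise.

    Returns ``(expression genes x samples, phenotype, catalog, signal set
    name or None)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 2_0130_701)))
    corr = simulation.build_correlation_matrix(set_size, p1, p2, rho)
    L = np.linalg.cholesky(corr)
    blocks = [rng.standard_normal((n, set_size)) @ L.T for _ in range(n_sets)]
    if nu > 0:
        mu = simulation.draw_mu(set_size, nu, rng)
        y_vals = blocks[0] @ mu + rng.standard_normal(n)
        signal = "SET000"
    else:
        y_vals = rng.standard_normal(n)
        signal = None
    samples = [f"S{i:03d}" for i in range(n)]
    gene_names: list[str] = []
    sets = []
    for k in range(n_sets):
        names = [f"SET{k:03d}_G{j:03d}" for j in range(set_size)]
        gene_names.extend(names)
        sets.append(GeneSet(f"SET{k:03d}", f"synthetic block {k}", tuple(names)))
    X = pd.DataFrame(np.hstack(blocks).T, index=gene_names, columns=samples)
    return X, pd.Series(y_vals, index=samples, name="phenotype"), GeneSetCollection(sets), signal


def make_fixture(
    outdir,
    n: int = 30,
    n_sets: int = 20,
    set_size: int = 40,
    p1: int = 10,
    p2: int = 10,
    rho: float = 0.3,
    nu: float = 0.0,
    seed: int = 0,
) -> FixturePaths:
    """Write the :func:`build_fixture_frames` trio to ``outdir`` as
    expression.tsv / phenotype.tsv / sets.gmt.  Byte-identical per seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X, y, coll, signal = build_fixture_frames(
        n=n, n_sets=n_sets, set_size=set_size, p1=p1, p2=p2, rho=rho, nu=nu, seed=seed
    )
    paths = FixturePaths(
        expression=outdir / "expression.tsv",
        phenotype=outdir / "phenotype.tsv",
        gmt=outdir / "sets.gmt",
        signal_set=signal,
    )
    write_expression(X, paths.expression)
    write_phenotype(y, paths.phenotype)
    write_gmt(coll, paths.gmt)
    return paths
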