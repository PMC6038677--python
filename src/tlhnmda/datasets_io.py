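"""Containers and TSV I/O for the triple-layer association data.

The model couples three entity layers — diseases, miRNAs and lncRNAs —
through two binary bipartite matrices (disease x miRNA associations ``A``,
miRNA x lncRNA interactions ``B``) and a MeSH-style disease DAG from which
semantic similarities are derived.  Everything on disk is plain TSV:
two-column edge lists for the bipartite layers and the DAG, and labeled
matrices (first row / first column are labels, ``NA`` marks undefined
entries) for similarity and score matrices.

Label order is sorted-lexicographic everywhere so matrix orientation is
deterministic across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BipartiteAssociations",
    "SimilarityMatrix",
    "DiseaseDAG",
    "read_bipartite_edges",
    "harmonize_lncrna_layer",
    "read_disease_dag",
    "write_disease_dag",
    "write_matrix",
    "read_matrix",
]

_SYMMETRY_TOL = 1e-10


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass(frozen=True)
class BipartiteAssociations:
    """Labeled binary matrix linking two entity layers.

    Rows and columns carry entity identifiers; ``matrix[i, j] == 1`` means
    the pair (row i, column j) is a known association/interaction.
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape != (len(self.row_labels), len(self.col_labels)):
            raise DataError(
                f"matrix shape {m.shape} does not match labels "
                f"({len(self.row_labels)} x {len(self.col_labels)})"
            )
        if len(set(self.row_labels)) != len(self.row_labels):
            raise DataError("duplicate row labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise DataError("duplicate column labels")
        if not np.isin(m, (0, 1)).all():
            raise DataError("bipartite matrix entries must be 0 or 1")
        object.__setattr__(self, "matrix", m.astype(np.int8))
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))

    @cached_property
    def row_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.row_labels)}

    @cached_property
    def col_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.col_labels)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def n_positives(self) -> int:
        return int(self.matrix.sum())


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square labeled similarity matrix with a coverage mask.

    ``coverage[i, j]`` is True where the similarity is defined; undefined
    entries (e.g. functional similarity between miRNAs with no annotated
    diseases) serialize as ``NA`` and are skipped by consumers.
    """

    labels: tuple[str, ...]
    matrix: np.ndarray
    coverage: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if m.shape != (n, n):
            raise DataError(f"similarity matrix must be {n}x{n}, got {m.shape}")
        if len(set(self.labels)) != n:
            raise DataError("duplicate labels")
        cov = self.coverage
        cov = np.ones((n, n), dtype=bool) if cov is None else np.asarray(cov, dtype=bool)
        if cov.shape != (n, n):
            raise DataError("coverage mask shape mismatch")
        if not np.array_equal(cov, cov.T):
            raise DataError("coverage mask must be symmetric")
        both = cov & cov.T
        if np.abs(np.where(both, m - m.T, 0.0)).max(initial=0.0) > _SYMMETRY_TOL:
            raise DataError("similarity matrix not symmetric within 1e-10")
        defined = m[cov]
        if defined.size and (defined.min() < -_SYMMETRY_TOL or defined.max() > 1 + _SYMMETRY_TOL):
            raise DataError("defined similarity entries must lie in [0, 1]")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "coverage", cov)
        object.__setattr__(self, "labels", tuple(self.labels))

    @cached_property
    def index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n(self) -> int:
        return len(self.labels)

    def value(self, a: str, b: str) -> float:
        return float(self.matrix[self.index[a], self.index[b]])


@dataclass(frozen=True)
class DiseaseDAG:
    """Rooted acyclic child->parent graph over disease terms.

    For a disease ``D``, ``ancestors(D)`` returns T(D): D itself plus every
    ancestor reachable through child->parent edges.  ``dag_membership[d]``
    is the set of diseases D whose DAG contains d, i.e. {D : d in T(D)} —
    the count used by semantic similarity model 2.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        nodeset = set(self.nodes)
        if len(nodeset) != len(self.nodes):
            raise DataError("duplicate disease identifiers")
        for child, parent in self.edges:
            if child == parent:
                raise DataError(f"self-edge on {child!r}")
            if child not in nodeset or parent not in nodeset:
                raise DataError(f"edge ({child!r}, {parent!r}) references unknown node")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
            raise DataError(f"cycle detected in disease DAG: {path}")
        object.__setattr__(self, "nodes", tuple(sorted(self.nodes)))
        object.__setattr__(self, "edges", frozenset(self.edges))

    @cached_property
    def _parents(self) -> dict[str, tuple[str, ...]]:
        p: dict[str, list[str]] = {n: [] for n in self.nodes}
        for child, parent in self.edges:
            p[child].append(parent)
        return {n: tuple(sorted(v)) for n, v in p.items()}

    @cached_property
    def _children(self) -> dict[str, tuple[str, ...]]:
        c: dict[str, list[str]] = {n: [] for n in self.nodes}
        for child, parent in self.edges:
            c[parent].append(child)
        return {n: tuple(sorted(v)) for n, v in c.items()}

    def parents(self, d: str) -> tuple[str, ...]:
        return self._parents[d]

    def children(self, d: str) -> tuple[str, ...]:
        return self._children[d]

    @cached_property
    def _ancestor_sets(self) -> dict[str, frozenset[str]]:
        memo: dict[str, frozenset[str]] = {}

        def anc(d: str) -> frozenset[str]:
            if d not in memo:
                out: set[str] = {d}
                for p in self._parents[d]:
                    out |= anc(p)
                memo[d] = frozenset(out)
            return memo[d]

        for n in self.nodes:
            anc(n)
        return memo

    def ancestors(self, d: str) -> frozenset[str]:
        """T(D): the disease itself plus all its DAG ancestors."""
        if d not in self._ancestor_sets:
            raise DataError(f"unknown disease {d!r}")
        return self._ancestor_sets[d]

    @cached_property
    def dag_membership(self) -> dict[str, frozenset[str]]:
        """For each d, the set of diseases D with d in T(D)."""
        member: dict[str, set[str]] = {n: set() for n in self.nodes}
        for D in self.nodes:
            for d in self.ancestors(D):
                member[d].add(D)
        return {n: frozenset(s) for n, s in member.items()}

    @cached_property
    def roots(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if not self._parents[n])


def read_bipartite_edges(
    path: str | Path,
    row_universe: Sequence[str] | None = None,
    col_universe: Sequence[str] | None = None,
) -> BipartiteAssociations:
    """Read a two-column TSV edge list into a binary labeled matrix.

    Each line is ``row_entity<TAB>col_entity``; repeated pairs collapse to a
    single 1.  If a universe is supplied, pairs outside it are filtered out
    and the label set is the universe itself; otherwise labels are the
    observed identifiers.  Labels are sorted lexicographically.
    """
    for uni, which in ((row_universe, "row"), (col_universe, "col")):
        if uni is not None and len(set(uni)) != len(list(uni)):
            raise DataError(f"{which} universe contains duplicates")
    pairs: set[tuple[str, str]] = set()
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise DataError(f"{path}: malformed line {lineno}: {line!r}")
            n_lines += 1
            pairs.add((fields[0].strip(), fields[1].strip()))
    if n_lines > len(pairs):
        logger.info("collapsed %d duplicate edge lines in %s", n_lines - len(pairs), path)
    if row_universe is not None:
        kept = {(r, c) for r, c in pairs if r in set(row_universe)}
        if len(kept) < len(pairs):
            logger.info("filtered %d pairs outside row universe", len(pairs) - len(kept))
        pairs = kept
        rows = sorted(row_universe)
    else:
        rows = sorted({r for r, _ in pairs})
    if col_universe is not None:
        kept = {(r, c) for r, c in pairs if c in set(col_universe)}
        if len(kept) < len(pairs):
            logger.info("filtered %d pairs outside column universe", len(pairs) - len(kept))
        pairs = kept
        cols = sorted(col_universe)
    else:
        cols = sorted({c for _, c in pairs})
    mat = np.zeros((len(rows), len(cols)), dtype=np.int8)
    ri = {r: i for i, r in enumerate(rows)}
    ci = {c: i for i, c in enumerate(cols)}
    for r, c in pairs:
        mat[ri[r], ci[c]] = 1
    return BipartiteAssociations(tuple(rows), tuple(cols), mat)


def harmonize_lncrna_layer(
    b_raw: BipartiteAssociations,
    a: BipartiteAssociations,
    drop_isolated: bool = False,
) -> BipartiteAssociations:
    """Restrict the miRNA-lncRNA layer to miRNAs known to the disease layer.

    miRNAs of ``b_raw`` (rows) absent from ``a``'s miRNA columns are deleted
    so the two layers share a single miRNA vocabulary.  lncRNAs left with
    zero interactions are kept by default; ``drop_isolated=True`` removes
    them.
    """
    keep = [m for m in b_raw.row_labels if m in a.col_index]
    if not keep:
        raise DataError(
            "no miRNA shared between the lncRNA layer and the disease layer; "
            "the two layers cannot be coupled"
        )
    rows = [b_raw.row_index[m] for m in keep]
    mat = b_raw.matrix[rows, :]
    cols = list(b_raw.col_labels)
    removed = b_raw.n_positives() - int(mat.sum())
    if removed:
        logger.info("harmonization removed %d interactions of unknown miRNAs", removed)
    if drop_isolated:
        nz = mat.sum(axis=0) > 0
        cols = [c for c, flag in zip(cols, nz) if flag]
        mat = mat[:, nz]
    return BipartiteAssociations(tuple(keep), tuple(cols), mat)


def read_disease_dag(path: str | Path) -> DiseaseDAG:
    """Read a ``child<TAB>parent`` TSV file into a validated DiseaseDAG."""
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise DataError(f"{path}: malformed line {lineno}: {line!r}")
            child, parent = fields[0].strip(), fields[1].strip()
            if child == parent:
                raise DataError(f"{path}: self-edge {child!r} at line {lineno}")
            edges.add((child, parent))
            nodes.update((child, parent))
    return DiseaseDAG(tuple(sorted(nodes)), frozenset(edges))


def write_disease_dag(dag: DiseaseDAG, path: str | Path) -> None:
    with open(path, "w") as fh:
        for child, parent in sorted(dag.edges):
            fh.write(f"{child}\t{parent}\n")


_KIND_TAGS = {"similarity": "#similarity", "bipartite": "#bipartite"}


def write_matrix(m: SimilarityMatrix | BipartiteAssociations, path: str | Path) -> None:
    """Serialize a labeled matrix to TSV.

    The corner cell tags the type so :func:`read_matrix` can round-trip
    without being told.  Undefined similarity entries are written as ``NA``.
    Numeric values use 17 significant digits (lossless for float64).
    """
    if isinstance(m, SimilarityMatrix):
        vals = m.matrix.astype(object)
        vals[~m.coverage] = None
        df = pd.DataFrame(vals, index=list(m.labels), columns=list(m.labels))
        tag = _KIND_TAGS["similarity"]
    elif isinstance(m, BipartiteAssociations):
        df = pd.DataFrame(m.matrix, index=list(m.row_labels), columns=list(m.col_labels))
        tag = _KIND_TAGS["bipartite"]
    else:
        raise TypeError(f"cannot serialize {type(m).__name__}")
    df.index.name = tag
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def read_matrix(
    path: str | Path, kind: str | None = None
) -> SimilarityMatrix | BipartiteAssociations:
    """Read a TSV written by :func:`write_matrix`.

    ``kind`` ("similarity" or "bipartite") overrides the corner-cell tag.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    corner = df.index.name or ""
    if kind is None:
        for k, tag in _KIND_TAGS.items():
            if corner == tag:
                kind = k
        if kind is None:
            raise DataError(f"{path}: unknown matrix type tag {corner!r}")
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    values = df.to_numpy(dtype=float)
    if kind == "similarity":
        if rows != cols:
            raise DataError(f"{path}: similarity matrix requires identical row/column labels")
        cov = ~np.isnan(values)
        return SimilarityMatrix(tuple(rows), np.where(cov, values, 0.0), cov)
    if kind == "bipartite":
        if np.isnan(values).any():
            raise DataError(f"{path}: NA not allowed in a bipartite matrix")
        return BipartiteAssociations(tuple(rows), tuple(cols), values)
    raise DataError(f"unknown matrix kind {kind!r}")
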