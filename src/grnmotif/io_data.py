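"""Expression-matrix and edge-list I/O, gene filtering and HVG selection.

The expression matrix is the standard genes-by-cells delimited-text layout
(first column gene identifiers, header row cell identifiers).  Networks are
two-column regulator/target edge lists.  Gene identifiers are matched
case-insensitively between matrix and network because public benchmark
networks and matrices frequently disagree in case; the original case of the
matrix is preserved for output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

CellOrderKind = Literal["unordered", "pseudotime", "timecourse"]


class ExpressionError(ValueError):
    """Raised for malformed or inconsistent expression input."""


class EdgeListError(ValueError):
    """Raised for malformed or unresolvable network input."""


@dataclass
class ExpressionMatrix:
    """Non-negative genes x cells expression values with identifiers.

    Columns are in collection / pseudo-temporal order when
    ``cell_order_kind`` is not ``"unordered"``; all downstream encoding
    consumes cells in column order.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_cells), float64, >= 0
    cell_order_kind: CellOrderKind = "unordered"
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ExpressionError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ExpressionError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if np.any(self.values < 0):
            raise ExpressionError("expression values must be non-negative")
        keys = [g.lower() for g in self.gene_ids]
        if len(set(keys)) != len(keys):
            seen: set[str] = set()
            dups = sorted({k for k in keys if k in seen or seen.add(k)})
            raise ExpressionError(
                f"duplicated gene ids after case normalization: {dups}"
            )
        self._index = {k: i for i, k in enumerate(keys)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id.lower() in self._index

    def row_index(self, gene_id: str) -> int:
        try:
            return self._index[gene_id.lower()]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def vector(self, gene_id: str) -> np.ndarray:
        """Expression vector of one gene across cells, in column order."""
        return self.values[self.row_index(gene_id)]

    def subset(self, gene_ids: list[str]) -> "ExpressionMatrix":
        rows = [self.row_index(g) for g in gene_ids]
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[r] for r in rows],
            cell_ids=list(self.cell_ids),
            values=self.values[rows],
            cell_order_kind=self.cell_order_kind,
        )


@dataclass
class EdgeList:
    """Directed regulator -> target ground-truth pairs."""

    edges: set[tuple[str, str]]
    tf_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.edges = {(a.lower(), b.lower()) for a, b in self.edges}
        if any(a == b for a, b in self.edges):
            raise EdgeListError("self-loop edge present")
        sources = {a for a, _ in self.edges}
        self.tf_ids = {t.lower() for t in self.tf_ids} | sources

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def targets_of(self, tf: str) -> set[str]:
        tf = tf.lower()
        return {b for a, b in self.edges if a == tf}

    def resolve(self, m: ExpressionMatrix) -> tuple["EdgeList", int]:
        """Drop edges whose genes are absent from ``m``.

        Returns the resolved edge list and the number of dropped edges.
        """
        kept = {(a, b) for a, b in self.edges if a in m and b in m}
        dropped = len(self.edges) - len(kept)
        tfs = {t for t in self.tf_ids if t in m}
        return EdgeList(edges=kept, tf_ids=tfs), dropped


def read_expression_matrix(
    path,
    delimiter: str = ",",
    genes_in_rows: bool = True,
    cell_order_kind: CellOrderKind = "unordered",
) -> ExpressionMatrix:
    """Read a delimited genes x cells matrix with a header row of cell ids.

    The first column holds gene identifiers.  Set ``genes_in_rows=False``
    for the transposed layout (cells in rows).  Cell order is preserved
    exactly as in the file.
    """
    # round_trip parser: written matrices must re-read bitwise identical
    df = pd.read_csv(path, sep=delimiter, index_col=0, float_precision="round_trip")
    if not genes_in_rows:
        df = df.T
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise ExpressionError(f"non-numeric expression value in {path}: {exc}") from exc
    if np.isnan(values).any():
        r, c = map(int, np.argwhere(np.isnan(values))[0])
        raise ExpressionError(
            f"missing/non-numeric value at gene {df.index[r]!r}, cell {df.columns[c]!r}"
        )
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        cell_ids=[str(c) for c in df.columns],
        values=values,
        cell_order_kind=cell_order_kind,
    )


def write_expression_matrix(m: ExpressionMatrix, path, delimiter: str = ",") -> None:
    df = pd.DataFrame(m.values, index=m.gene_ids, columns=m.cell_ids)
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def read_edge_list(
    path,
    delimiter: str = ",",
    matrix: ExpressionMatrix | None = None,
) -> tuple[EdgeList, int]:
    """Read a two-column (regulator, target) edge list.

    A header line is detected and skipped when its tokens do not look like a
    resolvable pair (both resolvable against ``matrix`` when supplied, else
    when the first line repeats common header words).  Returns the
    de-duplicated edge list and the number of dropped duplicate lines.
    Passing ``matrix`` makes unresolvable identifiers an error.
    """
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(delimiter)]
            if len(parts) < 2:
                raise EdgeListError(f"{path} line {ln + 1}: fewer than 2 columns")
            rows.append((parts[0], parts[1]))
    if not rows:
        warnings.warn(f"edge list {path} is empty", stacklevel=2)
        return EdgeList(edges=set()), 0
    header_words = {"tf", "regulator", "source", "gene1", "target", "gene2", "gene"}
    first = rows[0]
    is_header = {first[0].lower(), first[1].lower()} & header_words != set()
    if (
        matrix is not None
        and len(rows) > 1
        and (first[0] not in matrix or first[1] not in matrix)
    ):
        is_header = True
    if is_header:
        rows = rows[1:]
    if matrix is not None:
        bad = sorted({g for pair in rows for g in pair if g not in matrix})
        if bad:
            raise EdgeListError(f"edge list ids absent from matrix: {bad}")
    edges = {(a.lower(), b.lower()) for a, b in rows}
    n_dup = len(rows) - len(edges)
    return EdgeList(edges=edges), n_dup


def write_edge_list(net: EdgeList, path, delimiter: str = ",") -> None:
    with open(path, "w") as fh:
        fh.write(delimiter.join(("regulator", "target")) + "\n")
        for a, b in sorted(net.edges):
            fh.write(delimiter.join((a, b)) + "\n")


def filter_genes(m: ExpressionMatrix, min_cell_fraction: float = 0.1) -> ExpressionMatrix:
    """Drop genes expressed in fewer than ``min_cell_fraction`` of cells.

    "Fewer than" is strict: a gene nonzero in exactly
    ``ceil(min_cell_fraction * n_cells)`` cells is retained.
    """
    if not 0.0 <= min_cell_fraction <= 1.0:
        raise ValueError("min_cell_fraction must be in [0, 1]")
    threshold = math.ceil(min_cell_fraction * m.n_cells)
    n_nonzero = (m.values > 0).sum(axis=1)
    keep = [g for g, n in zip(m.gene_ids, n_nonzero) if n >= threshold]
    if not keep:
        raise ExpressionError("gene filtering removed every gene")
    return m.subset(keep)


def hvg_scores(m: ExpressionMatrix) -> np.ndarray:
    """Per-gene dispersion score: variance of log1p expression."""
    return np.log1p(m.values).var(axis=1)


def select_hvg(
    m: ExpressionMatrix,
    n_top: int,
    force_keep: set[str] | None = None,
) -> ExpressionMatrix:
    """Keep the ``n_top`` most variable genes (variance of log1p values).

    Ties break lexicographically on the gene id for determinism.  Genes in
    ``force_keep`` (e.g. ground-truth TFs) are retained in addition to the
    top set.  Row order of the original matrix is preserved.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if n_top > m.n_genes:
        warnings.warn(
            f"n_top={n_top} exceeds gene count {m.n_genes}; keeping all genes",
            stacklevel=2,
        )
        return m.subset(list(m.gene_ids))
    scores = hvg_scores(m)
    order = sorted(range(m.n_genes), key=lambda i: (-scores[i], m.gene_ids[i].lower()))
    chosen = {m.gene_ids[i].lower() for i in order[:n_top]}
    if force_keep:
        chosen |= {g.lower() for g in force_keep if g in m}
    keep = [g for g in m.gene_ids if g.lower() in chosen]
    return m.subset(keep)


def log1p_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Return a copy with log1p-transformed values (default pre-encoding step)."""
    return ExpressionMatrix(
        gene_ids=list(m.gene_ids),
        cell_ids=list(m.cell_ids),
        values=np.log1p(m.values),
        cell_order_kind=m.cell_order_kind,
    )
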