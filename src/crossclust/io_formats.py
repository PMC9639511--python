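"""Readers and writers for every on-disk artifact the pipeline touches.

All formats are plain text: MatrixMarket (counts), TSV (identifier
sidecars, cluster labels, ortholog pairs, marker tables), GMT (gene
sets), RNK (ranked lists), JSON (synthetic truth, results, metadata).
Every writer/reader pair round-trips to equality; floats are serialized
with shortest-repr precision, so the round-trip is exact.

Coordinates are 0-based internally; MatrixMarket files stay 1-based on
disk as the format requires.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

__all__ = [
    "FormatError",
    "CountMatrix",
    "ClusterLabels",
    "OrthologTable",
    "GeneSetCollection",
    "RankedList",
    "MARKER_COLUMNS",
    "read_count_matrix",
    "write_count_matrix",
    "read_cluster_labels",
    "write_cluster_labels",
    "read_ortholog_table",
    "write_ortholog_table",
    "read_gene_sets_gmt",
    "write_gene_sets_gmt",
    "read_ranked_list_rnk",
    "write_ranked_list_rnk",
    "read_marker_table",
    "write_marker_table",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with identifier sidecars."""

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix  # genes x cells, non-negative integers
    species: str = ""

    def __post_init__(self) -> None:
        _check_unique(self.genes, "gene")
        _check_unique(self.cells, "cell")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise FormatError("negative entry in count matrix")
            if not np.issubdtype(data.dtype, np.integer) and np.any(data != np.floor(data)):
                raise FormatError("non-integer entry in count matrix")
        self.counts = self.counts.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class ClusterLabels:
    """Per-cell cluster assignment; ``clusters`` ordered by first appearance."""

    assignment: dict[str, str]
    clusters: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.clusters:
            seen: list[str] = []
            for c in self.assignment.values():
                if c not in seen:
                    seen.append(c)
            self.clusters = seen
        _check_unique(self.clusters, "cluster")

    def cells_of(self, cluster: str) -> list[str]:
        return [cell for cell, c in self.assignment.items() if c == cluster]

    def validate_with(self, matrix: CountMatrix) -> None:
        """Check label/matrix consistency and the >= 2 cells per cluster rule."""
        missing = [c for c in matrix.cells if c not in self.assignment]
        if missing:
            raise FormatError(f"cells without cluster label: {missing[:5]}")
        extra = set(self.assignment) - set(matrix.cells)
        if extra:
            raise FormatError(f"labels for unknown cells: {sorted(extra)[:5]}")
        sizes: dict[str, int] = {}
        for c in self.assignment.values():
            sizes[c] = sizes.get(c, 0) + 1
        small = [c for c, n in sizes.items() if n < 2]
        if small:
            raise FormatError(f"clusters with fewer than 2 cells: {small}")


@dataclass
class OrthologTable:
    """Ordered (source_gene, target_gene) pairs; exact duplicates collapsed."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        deduped: list[tuple[str, str]] = []
        for s, t in self.pairs:
            if not s or not t:
                raise FormatError(f"empty identifier in ortholog pair ({s!r}, {t!r})")
            if (s, t) not in seen:
                seen.add((s, t))
                deduped.append((s, t))
        self.pairs = deduped

    def source_to_targets(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, t in self.pairs:
            out.setdefault(s, []).append(t)
        return out

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class GeneSetCollection:
    """Named gene sets in the target-species namespace (GMT-serializable)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            _check_unique(members, f"member of set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class RankedList:
    """Strictly ordered (gene, score) pairs: score descending, gene id ascending on ties."""

    entries: tuple[tuple[str, float], ...]
    metric: str = "signedP"

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.entries]
        _check_unique(genes, "ranked-list gene")
        for (g1, s1), (g2, s2) in zip(self.entries, self.entries[1:]):
            if s1 < s2 or (s1 == s2 and g1 >= g2):
                raise FormatError(
                    f"ranked list not in (score desc, gene asc) order at {g1!r}/{g2!r}"
                )

    @classmethod
    def from_scores(cls, scores: Mapping[str, float] | Iterable[tuple[str, float]],
                    metric: str = "signedP") -> "RankedList":
        items = list(scores.items()) if isinstance(scores, Mapping) else list(scores)
        genes = [g for g, _ in items]
        _check_unique(genes, "ranked-list gene")
        items.sort(key=lambda gs: (-gs[1], gs[0]))
        return cls(entries=tuple((g, float(s)) for g, s in items), metric=metric)

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.entries], dtype=float)

    def __len__(self) -> int:
        return len(self.entries)


#: column order contract for marker tables on disk
MARKER_COLUMNS = ["cluster", "gene", "avg_logFC", "U", "z", "p", "padj", "pct_in", "pct_out"]


# ---------------------------------------------------------------------------
# count matrices (MatrixMarket + sidecars)
# ---------------------------------------------------------------------------


def _read_id_file(path: Path | str, what: str) -> list[str]:
    ids = [line.rstrip("\n") for line in Path(path).read_text().splitlines()]
    ids = [x for x in ids if x != ""]
    _check_unique(ids, what)
    return ids


def read_count_matrix(mtx_path: Path | str, genes_path: Path | str,
                      cells_path: Path | str, species: str = "") -> CountMatrix:
    """Read a MatrixMarket coordinate file plus one-identifier-per-line sidecars."""
    genes = _read_id_file(genes_path, "gene")
    cells = _read_id_file(cells_path, "cell")
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except ValueError as exc:
        raise FormatError(f"invalid MatrixMarket file {mtx_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.shape[0] != len(genes):
        raise FormatError(
            f"MTX declares {mat.shape[0]} rows but gene sidecar has {len(genes)} entries"
        )
    if mat.shape[1] != len(cells):
        raise FormatError(
            f"MTX declares {mat.shape[1]} columns but cell sidecar has {len(cells)} entries"
        )
    if mat.data.size:
        if np.any(mat.data < 0):
            raise FormatError(f"negative entry in {mtx_path}")
        if not np.issubdtype(mat.data.dtype, np.integer) and np.any(mat.data != np.floor(mat.data)):
            raise FormatError(f"non-integer entry in {mtx_path}")
    return CountMatrix(genes=genes, cells=cells, counts=mat.tocsr(), species=species)


def write_count_matrix(matrix: CountMatrix, mtx_path: Path | str,
                       genes_path: Path | str, cells_path: Path | str) -> None:
    coo = matrix.counts.tocoo()
    # canonical entry order (row-major) so output bytes are reproducible
    order = np.lexsort((coo.col, coo.row))
    coo = sp.coo_matrix((coo.data[order], (coo.row[order], coo.col[order])), shape=coo.shape)
    buf = io.BytesIO()
    scipy.io.mmwrite(buf, coo, field="integer", symmetry="general")
    Path(mtx_path).write_bytes(buf.getvalue())
    Path(genes_path).write_text("".join(g + "\n" for g in matrix.genes))
    Path(cells_path).write_text("".join(c + "\n" for c in matrix.cells))


# ---------------------------------------------------------------------------
# cluster labels
# ---------------------------------------------------------------------------


def read_cluster_labels(path: Path | str) -> ClusterLabels:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty label file (header required)")
    assignment: dict[str, str] = {}
    for i, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise FormatError(f"{path}: malformed label row at line {i}: {line!r}")
        cell, cluster = parts
        if cell in assignment:
            raise FormatError(f"{path}: duplicate cell {cell!r} at line {i}")
        assignment[cell] = cluster
    return ClusterLabels(assignment=assignment)


def write_cluster_labels(labels: ClusterLabels, path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write("cell\tcluster\n")
        for cell, cluster in labels.assignment.items():
            fh.write(f"{cell}\t{cluster}\n")


# ---------------------------------------------------------------------------
# ortholog table
# ---------------------------------------------------------------------------


def read_ortholog_table(path: Path | str) -> OrthologTable:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty ortholog table (header required)")
    pairs: list[tuple[str, str]] = []
    for i, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise FormatError(f"{path}: malformed ortholog row at line {i}: {line!r}")
        pairs.append((parts[0], parts[1]))
    return OrthologTable(pairs=pairs)


def write_ortholog_table(table: OrthologTable, path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write("source_gene\ttarget_gene\n")
        for s, t in table.pairs:
            fh.write(f"{s}\t{t}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def write_gene_sets_gmt(collection: GeneSetCollection, path: Path | str) -> None:
    """One set per line: name TAB description TAB member TAB member ..."""
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            desc = collection.descriptions.get(name, "")
            for token in [name, desc, *members]:
                if "\t" in token or "\n" in token:
                    raise FormatError(
                        f"GMT cannot represent tab/newline inside {token!r} (set {name!r})"
                    )
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gene_sets_gmt(path: Path | str) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: GMT line {i} has fewer than 3 fields")
        name, desc, *members = parts
        if name in sets:
            raise FormatError(f"{path}: duplicate gene set {name!r} at line {i}")
        sets[name] = members
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


# ---------------------------------------------------------------------------
# RNK ranked lists
# ---------------------------------------------------------------------------


def write_ranked_list_rnk(ranked: RankedList, path: Path | str) -> None:
    """gene TAB score per line, descending score; shortest-repr float precision."""
    with open(path, "w") as fh:
        for gene, score in ranked.entries:
            if "\t" in gene or "\n" in gene:
                raise FormatError(f"RNK cannot represent tab/newline inside {gene!r}")
            fh.write(f"{gene}\t{score!r}\n")


def read_ranked_list_rnk(path: Path | str, metric: str = "signedP") -> RankedList:
    entries: list[tuple[str, float]] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}: malformed RNK row at line {i}: {line!r}")
        try:
            entries.append((parts[0], float(parts[1])))
        except ValueError as exc:
            raise FormatError(f"{path}: bad score at line {i}: {parts[1]!r}") from exc
    return RankedList(entries=tuple(entries), metric=metric)


# ---------------------------------------------------------------------------
# marker tables
# ---------------------------------------------------------------------------


def write_marker_table(table, path: Path | str) -> None:
    """TSV with the fixed column order; floats at shortest-repr precision."""
    import pandas as pd

    df = pd.DataFrame(table)
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"marker table missing columns: {missing}")
    df = df[MARKER_COLUMNS]
    with open(path, "w") as fh:
        fh.write("\t".join(MARKER_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            vals = [row.cluster, row.gene] + [repr(float(v)) for v in row[2:]]
            fh.write("\t".join(str(v) for v in vals) + "\n")


def read_marker_table(path: Path | str):
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"cluster": str, "gene": str},
                     float_precision="round_trip")
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: marker table missing columns: {missing}")
    return df[MARKER_COLUMNS]
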