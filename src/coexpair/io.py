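"""Readers and writers for the formats the pipeline touches.

Supported formats: the 10x-style MTX triplet (``matrix.mtx`` +
``barcodes.tsv`` + ``features.tsv``, gz-tolerant), and plain TSV tables for
cluster assignments, gene pairs, and cell-type markers.

MatrixMarket indices are 1-based; everything internal is 0-based. The
conversion lives entirely in this module (delegated to
:func:`scipy.io.mmread` / :func:`scipy.io.mmwrite`).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

from coexpair.errors import FormatError

logger = logging.getLogger(__name__)

MODALITIES = ("cell", "nucleus")

#: MTX orientation dialects. 10x writes genes as matrix rows.
DIALECTS = ("genes-as-rows", "genes-as-columns")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Sparse non-negative integer UMI counts, barcodes x genes.

    Parameters
    ----------
    counts
        Sparse matrix of shape ``(len(barcodes), len(genes))`` with
        non-negative integral entries.
    barcodes, genes
        Ordered, unique string labels for rows and columns.
    modality
        ``"cell"`` or ``"nucleus"``.
    library_id
        Free-form library tag.
    """

    counts: sp.csr_matrix
    barcodes: list[str]
    genes: list[str]
    modality: str = "cell"
    library_id: str = ""

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.barcodes = list(self.barcodes)
        self.genes = list(self.genes)
        if self.modality not in MODALITIES:
            raise FormatError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}"
            )
        n_bc, n_g = self.counts.shape
        if n_bc != len(self.barcodes):
            raise FormatError(
                f"matrix has {n_bc} rows but {len(self.barcodes)} barcodes"
            )
        if n_g != len(self.genes):
            raise FormatError(f"matrix has {n_g} columns but {len(self.genes)} genes")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("duplicate barcodes")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate gene ids")
        data = self.counts.data
        if data.size and data.min() < 0:
            raise FormatError("negative count entries")
        if data.size and not np.allclose(data, np.round(data)):
            raise FormatError("non-integer count entries")
        self.counts.data = np.asarray(np.round(data), dtype=np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def total_count(self) -> int:
        return int(self.counts.sum())

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def barcode_index(self) -> dict[str, int]:
        return {b: i for i, b in enumerate(self.barcodes)}

    def subset_barcodes(self, keep: Sequence[int]) -> "CountMatrix":
        """Row-subset preserving barcode order as given by ``keep``."""
        keep = list(keep)
        return CountMatrix(
            counts=self.counts[keep, :],
            barcodes=[self.barcodes[i] for i in keep],
            genes=self.genes,
            modality=self.modality,
            library_id=self.library_id,
        )

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        """Column-subset to the given genes, in the given order."""
        idx = self.gene_index()
        cols = [idx[g] for g in genes]
        return CountMatrix(
            counts=self.counts[:, cols],
            barcodes=self.barcodes,
            genes=list(genes),
            modality=self.modality,
            library_id=self.library_id,
        )


@dataclass
class GenePairTable:
    """Ordered list of (geneA, geneB) pairs; order is never canonicalized."""

    pairs: list[tuple[str, str]]
    source: str = ""

    def __post_init__(self) -> None:
        self.pairs = [(str(a), str(b)) for a, b in self.pairs]
        for a, b in self.pairs:
            if a == b:
                raise FormatError(f"self-pair ({a}, {b}) not allowed")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.pairs)

    def genes(self) -> list[str]:
        """Unique genes in first-appearance order."""
        seen: dict[str, None] = {}
        for a, b in self.pairs:
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)


@dataclass
class ClusterAssignment:
    """Barcode -> cluster-id map; cluster ids are opaque strings."""

    labels: dict[str, str]
    cluster_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cluster_ids:
            seen: dict[str, None] = {}
            for c in self.labels.values():
                seen.setdefault(c)
            self.cluster_ids = list(seen)
        for c in self.cluster_ids:
            if c == "":
                raise FormatError("empty cluster id")

    def barcodes_of(self, cluster: str) -> list[str]:
        return [b for b, c in self.labels.items() if c == cluster]


@dataclass
class MarkerTable:
    """List of (gene id, cell-type label) marker entries."""

    entries: list[tuple[str, str]]

    def cell_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, t in self.entries:
            seen.setdefault(t)
        return list(seen)

    def markers_of(self, cell_type: str) -> list[str]:
        return [g for g, t in self.entries if t == cell_type]

    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g, _ in self.entries:
            seen.setdefault(g)
        return list(seen)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _find(dir: Path, stem: str) -> Path:
    """Locate ``stem`` or ``stem.gz`` in ``dir``."""
    for name in (stem, stem + ".gz"):
        p = dir / name
        if p.exists():
            return p
    raise FormatError(f"missing {stem}[.gz] in {dir}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_tsv_rows(path: Path, min_cols: int) -> list[tuple[int, list[str]]]:
    """Stream non-comment rows as (1-based line number, fields)."""
    rows: list[tuple[int, list[str]]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f.strip().strip('"') for f in line.split("\t")]
            if len(fields) < min_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {min_cols} tab-separated "
                    f"columns, got {len(fields)}"
                )
            rows.append((lineno, fields))
    logger.info("read %d rows from %s", len(rows), path)
    return rows


# ---------------------------------------------------------------------------
# 10x bundle
# ---------------------------------------------------------------------------


def read_10x(
    dir: str | Path,
    dialect: str = "genes-as-rows",
    modality: str = "cell",
    library_id: str = "",
) -> CountMatrix:
    """Read a 10x-style MTX bundle into a validated :class:`CountMatrix`.

    Gene orientation is normalized to barcodes x genes regardless of
    ``dialect``. ``features.tsv`` may have 1-3 columns; the first column is
    the gene id. A legacy ``genes.tsv`` is accepted in place of
    ``features.tsv``.
    """
    dir = Path(dir)
    if dialect not in DIALECTS:
        raise FormatError(f"dialect must be one of {DIALECTS}, got {dialect!r}")
    mtx_path = _find(dir, "matrix.mtx")
    barcodes_path = _find(dir, "barcodes.tsv")
    try:
        features_path = _find(dir, "features.tsv")
    except FormatError:
        features_path = _find(dir, "genes.tsv")

    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise FormatError(f"{mtx_path}: unreadable MatrixMarket file: {exc}") from exc

    barcodes = [f[0] for _, f in _read_tsv_rows(barcodes_path, 1)]
    genes = [f[0] for _, f in _read_tsv_rows(features_path, 1)]

    if dialect == "genes-as-rows":
        mat = mat.T
    mat = sp.csr_matrix(mat)
    if mat.shape != (len(barcodes), len(genes)):
        raise FormatError(
            f"{mtx_path}: matrix shape {mat.shape} (as barcodes x genes, "
            f"dialect {dialect!r}) does not match {len(barcodes)} barcodes x "
            f"{len(genes)} genes"
        )
    return CountMatrix(
        counts=mat,
        barcodes=barcodes,
        genes=genes,
        modality=modality,
        library_id=library_id,
    )


def write_10x(
    matrix: CountMatrix, dir: str | Path, dialect: str = "genes-as-rows"
) -> list[Path]:
    """Write a CountMatrix as matrix.mtx + barcodes.tsv + features.tsv."""
    dir = Path(dir)
    if dialect not in DIALECTS:
        raise FormatError(f"dialect must be one of {DIALECTS}, got {dialect!r}")
    dir.mkdir(parents=True, exist_ok=True)
    mat = matrix.counts.tocoo()
    if dialect == "genes-as-rows":
        mat = mat.T
    mtx_path = dir / "matrix.mtx"
    scipy.io.mmwrite(str(mtx_path), mat.astype(np.int64), field="integer")
    bc_path = dir / "barcodes.tsv"
    bc_path.write_text("".join(b + "\n" for b in matrix.barcodes))
    ft_path = dir / "features.tsv"
    ft_path.write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in matrix.genes)
    )
    return [mtx_path, bc_path, ft_path]


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def read_pairs(
    file: str | Path, genes: Sequence[str] | None = None
) -> tuple[GenePairTable, dict]:
    """Read a gene-pair TSV restricted to a gene universe.

    Drops (with reasons in the report) pairs containing an unknown gene,
    self-pairs, and exact ordered duplicates (first occurrence kept).
    Within-pair order and pair order are preserved exactly as read.
    """
    file = Path(file)
    rows = _read_tsv_rows(file, 2)
    if not rows:
        raise FormatError(f"{file}: empty pair table")
    universe = set(genes) if genes is not None else None
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    dropped: list[dict] = []
    for lineno, fields in rows:
        a, b = fields[0], fields[1]
        if a == b:
            dropped.append({"line": lineno, "pair": (a, b), "reason": "self_pair"})
            continue
        if universe is not None and (a not in universe or b not in universe):
            dropped.append({"line": lineno, "pair": (a, b), "reason": "unknown_gene"})
            continue
        if (a, b) in seen:
            dropped.append({"line": lineno, "pair": (a, b), "reason": "duplicate"})
            continue
        seen.add((a, b))
        pairs.append((a, b))
    report = {
        "n_read": len(rows),
        "n_retained": len(pairs),
        "n_dropped": len(dropped),
        "dropped": dropped,
    }
    return GenePairTable(pairs=pairs, source=str(file)), report


def write_pairs(pairs: GenePairTable, file: str | Path) -> Path:
    file = Path(file)
    file.write_text("".join(f"{a}\t{b}\n" for a, b in pairs))
    return file


def read_clusters(file: str | Path) -> ClusterAssignment:
    """Read a barcode TAB cluster-id table.

    Unknown barcodes are reported when joined against a matrix, not here.
    """
    file = Path(file)
    rows = _read_tsv_rows(file, 2)
    labels: dict[str, str] = {}
    order: dict[str, None] = {}
    for lineno, fields in rows:
        bc, cl = fields[0], fields[1]
        if cl == "":
            raise FormatError(f"{file}:{lineno}: empty cluster id for {bc!r}")
        if bc in labels and labels[bc] != cl:
            raise FormatError(
                f"{file}:{lineno}: barcode {bc!r} assigned to both "
                f"{labels[bc]!r} and {cl!r}"
            )
        labels[bc] = cl
        order.setdefault(cl)
    return ClusterAssignment(labels=labels, cluster_ids=list(order))


def write_clusters(assignment: ClusterAssignment, file: str | Path) -> Path:
    file = Path(file)
    file.write_text(
        "".join(f"{b}\t{c}\n" for b, c in assignment.labels.items())
    )
    return file


def read_markers(file: str | Path) -> MarkerTable:
    """Read a gene TAB cell-type table; exact duplicates are dropped."""
    file = Path(file)
    rows = _read_tsv_rows(file, 2)
    entries: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for lineno, fields in rows:
        g, t = fields[0], fields[1]
        if t == "":
            raise FormatError(f"{file}:{lineno}: empty cell type for {g!r}")
        if (g, t) in seen:
            continue
        seen.add((g, t))
        entries.append((g, t))
    return MarkerTable(entries=entries)


def write_markers(markers: MarkerTable, file: str | Path) -> Path:
    file = Path(file)
    file.write_text("".join(f"{g}\t{t}\n" for g, t in markers.entries))
    return file
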