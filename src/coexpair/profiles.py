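"""Normalization, per-cluster average expression, dot-plot statistics,
marker-based cluster annotation, and barcode-majority label transfer.

Normalization is library-size scaling to a fixed total (default 1e4)
followed by log1p. Cluster averages are taken on the de-logged
(``expm1``) normalized scale, which reproduces the standard
average-expression behaviour of single-cell toolkits; a raw-count
averaging mode is available for pipelines that work in UMI units.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from coexpair.errors import DataError
from coexpair.io import ClusterAssignment, CountMatrix, MarkerTable

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Normalized expression values (log1p scale), barcodes x genes."""

    values: sp.csr_matrix
    barcodes: list[str]
    genes: list[str]
    scale: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ClusterProfile:
    """Genes x clusters average-expression matrix."""

    avg: np.ndarray
    genes: list[str]
    clusters: list[str]
    n_entities: dict[str, int]
    norm_scale: float | None = None

    def __post_init__(self) -> None:
        if self.avg.shape != (len(self.genes), len(self.clusters)):
            raise DataError(
                f"profile shape {self.avg.shape} does not match "
                f"{len(self.genes)} genes x {len(self.clusters)} clusters"
            )

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.avg, index=self.genes, columns=self.clusters)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index_label="gene")
        return path


@dataclass
class DotPlotStat:
    """Per (gene, cluster) percent-expressing and mean expression.

    ``table`` has columns gene, cluster, pct_expressing (0..100, fraction
    of entities with a raw count > 0) and mean_expression (log1p scale).
    """

    table: pd.DataFrame
    unknown_genes: list[str] = field(default_factory=list)

    def get(self, gene: str, cluster: str) -> tuple[float, float]:
        row = self.table[
            (self.table["gene"] == gene) & (self.table["cluster"] == cluster)
        ]
        if row.empty:
            raise KeyError((gene, cluster))
        return float(row["pct_expressing"].iloc[0]), float(
            row["mean_expression"].iloc[0]
        )

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False)
        return path


@dataclass
class AnnotationEntry:
    label: str
    score: float
    supporting_markers: list[str]
    purity: float | None = None


@dataclass
class ClusterAnnotation:
    """Cluster -> (cell type, score, supporting markers)."""

    entries: dict[str, AnnotationEntry]

    def label_of(self, cluster: str) -> str:
        return self.entries[cluster].label

    def to_dict(self) -> dict:
        return {
            c: {
                "label": e.label,
                "score": e.score,
                "supporting_markers": e.supporting_markers,
                **({"purity": e.purity} if e.purity is not None else {}),
            }
            for c, e in self.entries.items()
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        return path

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("cluster\tlabel\tscore\tsupporting_markers\tpurity\n")
            for c, e in self.entries.items():
                purity = "" if e.purity is None else f"{e.purity:.4f}"
                fh.write(
                    f"{c}\t{e.label}\t{e.score:.6g}\t"
                    f"{','.join(e.supporting_markers)}\t{purity}\n"
                )
        return path


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def normalize(matrix: CountMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Scale each barcode to total ``scale``, then log1p.

    Zero-total barcodes are left at zero and logged.
    """
    if scale <= 0:
        raise DataError(f"scale must be > 0, got {scale}")
    if len(matrix.barcodes) == 0:
        raise DataError("normalize: empty matrix")
    totals = np.asarray(matrix.counts.sum(axis=1)).ravel().astype(float)
    zero = totals == 0
    if zero.any():
        logger.warning("normalize: %d zero-total barcodes left at zero", zero.sum())
    factors = np.divide(scale, totals, out=np.zeros_like(totals), where=~zero)
    values = sp.csr_matrix(matrix.counts, dtype=float)
    values = sp.diags(factors) @ values
    values.data = np.log1p(values.data)
    return ExpressionMatrix(
        values=values.tocsr(),
        barcodes=list(matrix.barcodes),
        genes=list(matrix.genes),
        scale=scale,
    )


def _match(
    barcodes: Sequence[str], assignment: ClusterAssignment
) -> tuple[dict[str, list[int]], list[str]]:
    """Group matrix row indices by cluster; drop empty clusters with warning."""
    rows_of: dict[str, list[int]] = {c: [] for c in assignment.cluster_ids}
    for i, b in enumerate(barcodes):
        c = assignment.labels.get(b)
        if c is not None:
            rows_of[c].append(i)
    kept = [c for c in assignment.cluster_ids if rows_of[c]]
    dropped = [c for c in assignment.cluster_ids if not rows_of[c]]
    if dropped:
        logger.warning("clusters with no matched barcodes dropped: %s", dropped)
    if not kept:
        raise DataError("assignment matches no barcode of the matrix")
    return {c: rows_of[c] for c in kept}, kept


def average_by_cluster(
    normalized: ExpressionMatrix | CountMatrix,
    assignment: ClusterAssignment,
) -> ClusterProfile:
    """Per-cluster mean expression, genes x clusters.

    Given an :class:`ExpressionMatrix`, averages ``expm1`` of the
    normalized values (de-logged normalized scale). Given a raw
    :class:`CountMatrix`, averages raw counts (UMI units).
    """
    raw = isinstance(normalized, CountMatrix)
    mat = normalized.counts if raw else normalized.values
    rows_of, clusters = _match(normalized.barcodes, assignment)
    G = mat.shape[1]
    avg = np.zeros((G, len(clusters)))
    for j, c in enumerate(clusters):
        sub = mat[rows_of[c], :]
        if not raw:
            sub = sub.copy()
            sub.data = np.expm1(sub.data)
        avg[:, j] = np.asarray(sub.mean(axis=0)).ravel()
    return ClusterProfile(
        avg=avg,
        genes=list(normalized.genes),
        clusters=clusters,
        n_entities={c: len(rows_of[c]) for c in clusters},
        norm_scale=None if raw else normalized.scale,
    )


def dotplot_stats(
    matrix: CountMatrix,
    normalized: ExpressionMatrix,
    assignment: ClusterAssignment,
    genes: Sequence[str],
) -> DotPlotStat:
    """Percent-of-entities-expressing and mean log1p expression per
    (gene, cluster). Unknown genes are reported and omitted."""
    idx = matrix.gene_index()
    known = [g for g in genes if g in idx]
    unknown = [g for g in genes if g not in idx]
    if unknown:
        logger.warning("dotplot_stats: unknown genes omitted: %s", unknown)
    rows_of, clusters = _match(matrix.barcodes, assignment)
    records = []
    for c in clusters:
        rows = rows_of[c]
        raw_sub = matrix.counts[rows, :]
        norm_sub = normalized.values[rows, :]
        n = len(rows)
        for g in known:
            col = idx[g]
            n_expr = int((raw_sub[:, col] > 0).sum())
            mean_expr = float(norm_sub[:, col].sum()) / n
            records.append(
                {
                    "gene": g,
                    "cluster": c,
                    "pct_expressing": 100.0 * n_expr / n,
                    "mean_expression": mean_expr,
                }
            )
    return DotPlotStat(table=pd.DataFrame.from_records(records), unknown_genes=unknown)


def annotate_clusters(
    stats: DotPlotStat, markers: MarkerTable
) -> ClusterAnnotation:
    """Label each cluster with the cell type whose markers score highest.

    Score = mean over the type's markers of the across-cluster z-score of
    mean_expression (constant genes get z = 0). Ties break by higher mean
    pct_expressing over the markers, then by lexicographically smaller
    label. A cluster in which every marker of every type has zero mean
    expression is labeled ``unassigned``.
    """
    if not markers.entries:
        raise DataError("annotate_clusters: empty marker table")
    tbl = stats.table
    clusters = sorted(tbl["cluster"].unique())
    mean_wide = tbl.pivot(index="gene", columns="cluster", values="mean_expression")
    pct_wide = tbl.pivot(index="gene", columns="cluster", values="pct_expressing")
    sd = mean_wide.std(axis=1, ddof=0)
    z = mean_wide.sub(mean_wide.mean(axis=1), axis=0).div(sd.replace(0.0, np.inf), axis=0)

    entries: dict[str, AnnotationEntry] = {}
    for c in clusters:
        candidates = []
        all_zero = True
        for t in markers.cell_types():
            present = [g for g in markers.markers_of(t) if g in mean_wide.index]
            if not present:
                continue
            if any(mean_wide.loc[g, c] > 0 for g in present):
                all_zero = False
            score = float(np.mean([z.loc[g, c] for g in present]))
            mean_pct = float(np.mean([pct_wide.loc[g, c] for g in present]))
            candidates.append((score, mean_pct, t, present))
        if not candidates or all_zero:
            entries[c] = AnnotationEntry("unassigned", float("nan"), [])
            continue
        # max score, then max pct, then lexicographically smallest label
        best = sorted(candidates, key=lambda x: (-x[0], -x[1], x[2]))[0]
        entries[c] = AnnotationEntry(best[2], best[0], best[3])
    return ClusterAnnotation(entries=entries)


def transfer_labels(
    source: ClusterAssignment,
    source_annotation: ClusterAnnotation,
    target: ClusterAssignment,
) -> ClusterAnnotation:
    """Transfer cell-type labels to a second clustering via shared barcodes.

    Each target cluster takes the majority cell type of its barcodes'
    source annotations; ties break to the lexicographically smaller label.
    ``purity`` is the majority fraction. Target clusters sharing no
    barcode with the source get ``unassigned``; fully disjoint barcode
    sets raise :class:`DataError`.
    """
    type_of_barcode = {
        b: source_annotation.label_of(c)
        for b, c in source.labels.items()
        if c in source_annotation.entries
    }
    shared_any = False
    entries: dict[str, AnnotationEntry] = {}
    for c in target.cluster_ids:
        votes: dict[str, int] = {}
        for b in target.barcodes_of(c):
            t = type_of_barcode.get(b)
            if t is not None:
                votes[t] = votes.get(t, 0) + 1
        if not votes:
            entries[c] = AnnotationEntry("unassigned", float("nan"), [], purity=0.0)
            continue
        shared_any = True
        n_shared = sum(votes.values())
        winner = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        entries[c] = AnnotationEntry(
            winner[0],
            float(winner[1]),
            [],
            purity=winner[1] / n_shared,
        )
    if not shared_any:
        raise DataError("transfer_labels: source and target share no barcode")
    return ClusterAnnotation(entries=entries)
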