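"""Outlier removal on per-barcode metrics and expression summaries.

The filter removes barcodes whose total UMI count or detected-gene count
falls outside the central ``level`` interval of the observed distribution,
on either metric. Two interval constructions are offered:

* ``percentile`` (default): empirical central interval, bounds at the
  ``(1-level)/2`` and ``(1+level)/2`` quantiles computed with linear
  interpolation between order statistics (numpy's default quantile method).
* ``gaussian``: mean +/- z * sd with z the two-sided normal quantile.

The percentile construction is the default because per-barcode UMI totals
are heavy-tailed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from coexpair.errors import ConfigError
from coexpair.io import CountMatrix

logger = logging.getLogger(__name__)

METHODS = ("percentile", "gaussian")


@dataclass
class QcSummary:
    """Per-barcode metrics and dataset-level expression summaries.

    Medians and the expressed-gene total are computed over retained
    barcodes only. ``n_retained + n_removed`` equals the input barcode
    count.
    """

    barcodes: list[str]
    total_umis: np.ndarray
    detected_genes: np.ndarray
    median_total_umis: float
    median_detected_genes: float
    total_expressed_genes: int
    n_retained: int
    n_removed: int
    removed_barcodes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "median_total_umis": self.median_total_umis,
            "median_detected_genes": self.median_detected_genes,
            "total_expressed_genes": self.total_expressed_genes,
            "n_retained": self.n_retained,
            "n_removed": self.n_removed,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        return path

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("barcode\ttotal_umis\tdetected_genes\n")
            for b, t, d in zip(self.barcodes, self.total_umis, self.detected_genes):
                fh.write(f"{b}\t{int(t)}\t{int(d)}\n")
        return path


def _barcode_metrics(matrix: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
    totals = np.asarray(matrix.counts.sum(axis=1)).ravel()
    detected = np.asarray((matrix.counts > 0).sum(axis=1)).ravel()
    return totals, detected


def summarize(matrix: CountMatrix) -> QcSummary:
    """Compute per-barcode and dataset expression summaries.

    ``total_expressed_genes`` counts genes with at least one count in at
    least one barcode. An empty matrix yields a NaN-median sentinel.
    """
    totals, detected = _barcode_metrics(matrix)
    n = len(matrix.barcodes)
    if n == 0:
        logger.warning("summarize: empty matrix, returning sentinel summary")
        return QcSummary(
            barcodes=[],
            total_umis=totals,
            detected_genes=detected,
            median_total_umis=float("nan"),
            median_detected_genes=float("nan"),
            total_expressed_genes=0,
            n_retained=0,
            n_removed=0,
        )
    expressed = int((np.asarray(matrix.counts.sum(axis=0)).ravel() > 0).sum())
    return QcSummary(
        barcodes=list(matrix.barcodes),
        total_umis=totals,
        detected_genes=detected,
        median_total_umis=float(np.median(totals)),
        median_detected_genes=float(np.median(detected)),
        total_expressed_genes=expressed,
        n_retained=n,
        n_removed=0,
    )


def _interval(x: np.ndarray, level: float, method: str) -> tuple[float, float]:
    if method == "percentile":
        lo = 100.0 * (1.0 - level) / 2.0
        return tuple(np.percentile(x, [lo, 100.0 - lo]))  # type: ignore[return-value]
    z = stats.norm.ppf((1.0 + level) / 2.0)
    m, s = float(np.mean(x)), float(np.std(x))
    return m - z * s, m + z * s


def filter_outliers(
    matrix: CountMatrix, level: float = 0.95, method: str = "percentile"
) -> tuple[CountMatrix, QcSummary]:
    """Remove barcodes outside the central ``level`` interval.

    A barcode is removed if its total UMI count OR its detected-gene count
    lies strictly outside the interval for that metric (two-sided, both
    metrics checked). Survivor order is preserved. The returned summary is
    computed on the retained barcodes.
    """
    if not 0.0 < level < 1.0:
        raise ConfigError(f"level must be in (0, 1), got {level}")
    if method not in METHODS:
        raise ConfigError(f"method must be one of {METHODS}, got {method!r}")
    if len(matrix.barcodes) == 0:
        raise ConfigError("filter_outliers: empty matrix")

    totals, detected = _barcode_metrics(matrix)
    keep = np.ones(len(matrix.barcodes), dtype=bool)
    for x in (totals, detected):
        lo, hi = _interval(x.astype(float), level, method)
        keep &= (x >= lo) & (x <= hi)

    kept_idx = np.flatnonzero(keep)
    removed = [matrix.barcodes[i] for i in np.flatnonzero(~keep)]
    filtered = matrix.subset_barcodes(kept_idx)
    summary = summarize(filtered)
    summary.n_removed = len(removed)
    summary.removed_barcodes = removed
    if not math.isnan(summary.median_detected_genes):
        logger.info(
            "qc: removed %d of %d barcodes (level=%.3g, method=%s)",
            len(removed),
            len(matrix.barcodes),
            level,
            method,
        )
    return filtered, summary
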