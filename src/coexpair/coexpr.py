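"""Per-cluster co-expressed-pair identification and Pearson correlation.

A pair is co-expressed in a cluster iff BOTH genes' average expression in
that cluster is at or above ``min_expression`` (inclusive, default 0.15).
The per-cluster correlation is the Pearson r across the retained pairs of
that cluster, with x = first-gene average and y = second-gene average —
i.e. within-cluster, across pairs. An alternative reading (per-pair
correlation across clusters) is available via ``mode="across_clusters"``.

Undefined correlations (fewer than 2 retained pairs, or zero variance on
either axis) are reported as NaN, never imputed.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from coexpair.errors import ConfigError, DataError
from coexpair.io import GenePairTable
from coexpair.profiles import ClusterProfile

logger = logging.getLogger(__name__)

PAIR_ORDERS = ("as_given", "symmetrized")
MODES = ("within_cluster", "across_clusters")


@dataclass
class CoexprConfig:
    """Settings of the co-expression filter and correlation."""

    min_expression: float = 0.15
    pair_order: str = "as_given"
    rounding: int = 1
    mode: str = "within_cluster"

    def validate(self) -> None:
        if self.min_expression < 0:
            raise ConfigError(
                f"min_expression must be >= 0, got {self.min_expression}"
            )
        if self.pair_order not in PAIR_ORDERS:
            raise ConfigError(
                f"pair_order must be one of {PAIR_ORDERS}, got {self.pair_order!r}"
            )
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.rounding < 0:
            raise ConfigError(f"rounding must be >= 0, got {self.rounding}")


@dataclass
class PairCoexprResult:
    """Per-cluster retained pairs, counts, percentages and Pearson r."""

    clusters: list[str]
    pairs: list[tuple[str, str]]
    #: cluster -> indices into ``pairs`` retained by the filter
    retained: dict[str, list[int]]
    n_coexpressed: dict[str, int]
    #: cluster -> Pearson r over retained pairs (NaN when undefined)
    pearson_r: dict[str, float]
    union_count: int
    total_pairs: int
    pct_per_cluster: dict[str, float]
    union_pct: float
    #: per-pair r across clusters; populated only in across_clusters mode
    per_pair_r: dict[tuple[str, str], float] = field(default_factory=dict)
    missing_genes: list[str] = field(default_factory=list)

    def defined_r(self) -> dict[str, float]:
        return {c: r for c, r in self.pearson_r.items() if not math.isnan(r)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": self.clusters,
                "n_coexpressed": [self.n_coexpressed[c] for c in self.clusters],
                "pct_coexpressed": [self.pct_per_cluster[c] for c in self.clusters],
                "pearson_r": [self.pearson_r[c] for c in self.clusters],
            }
        )

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "total_pairs": self.total_pairs,
            "union_count": self.union_count,
            "union_pct": self.union_pct,
            "clusters": {
                c: {
                    "n_coexpressed": self.n_coexpressed[c],
                    "pct_coexpressed": self.pct_per_cluster[c],
                    "pearson_r": None
                    if math.isnan(self.pearson_r[c])
                    else self.pearson_r[c],
                }
                for c in self.clusters
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return path


def pct(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals``."""
    if denominator <= 0:
        raise ConfigError(f"pct: denominator must be > 0, got {denominator}")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(numerator) * 100) / Decimal(denominator)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r, NaN when n < 2 or either axis has zero variance."""
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.pearsonr(x, y).statistic)


def coexpressed_pairs(
    profile: ClusterProfile,
    pairs: GenePairTable,
    config: CoexprConfig | None = None,
) -> PairCoexprResult:
    """Apply the minimum-expression filter and per-cluster correlation.

    Pair genes absent from the profile's gene universe are treated as
    zero expression and logged.
    """
    config = config or CoexprConfig()
    config.validate()
    if len(pairs) == 0:
        raise DataError("coexpressed_pairs: empty pair table")

    pair_list = list(pairs.pairs)
    if config.pair_order == "symmetrized":
        pair_list = [tuple(sorted(p)) for p in pair_list]

    gene_idx = profile.gene_index()
    missing = sorted(
        {g for p in pair_list for g in p if g not in gene_idx}
    )
    if missing:
        logger.warning(
            "coexpressed_pairs: %d pair genes missing from profile, "
            "treated as zero expression",
            len(missing),
        )

    n_pairs = len(pair_list)
    K = len(profile.clusters)
    # expression of each pair gene in each cluster; missing genes -> 0
    xa = np.zeros((n_pairs, K))
    xb = np.zeros((n_pairs, K))
    for i, (a, b) in enumerate(pair_list):
        if a in gene_idx:
            xa[i, :] = profile.avg[gene_idx[a], :]
        if b in gene_idx:
            xb[i, :] = profile.avg[gene_idx[b], :]

    t = config.min_expression
    keep = (xa >= t) & (xb >= t)  # pairs x clusters

    retained: dict[str, list[int]] = {}
    n_co: dict[str, int] = {}
    r_of: dict[str, float] = {}
    pcts: dict[str, float] = {}
    for j, c in enumerate(profile.clusters):
        idx = np.flatnonzero(keep[:, j])
        retained[c] = idx.tolist()
        n_co[c] = len(idx)
        r_of[c] = _pearson(xa[idx, j], xb[idx, j])
        pcts[c] = pct(len(idx), n_pairs, config.rounding)

    union = int(keep.any(axis=1).sum())
    result = PairCoexprResult(
        clusters=list(profile.clusters),
        pairs=pair_list,
        retained=retained,
        n_coexpressed=n_co,
        pearson_r=r_of,
        union_count=union,
        total_pairs=n_pairs,
        pct_per_cluster=pcts,
        union_pct=pct(union, n_pairs, config.rounding),
        missing_genes=missing,
    )
    if config.mode == "across_clusters":
        result.per_pair_r = {
            pair_list[i]: _pearson(
                xa[i, keep[i, :]], xb[i, keep[i, :]]
            )
            for i in range(n_pairs)
        }
    return result


def correlation_summary(result: PairCoexprResult) -> pd.DataFrame:
    """Per-cluster (cluster, n_coexpressed, r) plus min/max defined r.

    The min/max are stored in the frame's ``attrs`` under ``"r_min"`` and
    ``"r_max"``. An empty frame (with a warning) is returned when no
    cluster has a defined r.
    """
    defined = result.defined_r()
    if not defined:
        logger.warning("correlation_summary: no cluster has a defined r")
        frame = pd.DataFrame(columns=["cluster", "n_coexpressed", "pearson_r"])
        frame.attrs["r_min"] = float("nan")
        frame.attrs["r_max"] = float("nan")
        return frame
    frame = result.to_frame()
    frame.attrs["r_min"] = min(defined.values())
    frame.attrs["r_max"] = max(defined.values())
    return frame
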