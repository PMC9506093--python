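"""Random-gene-pair null model.

Random pairs are pushed through the *identical* filter + correlation code
path (:func:`coexpair.coexpr.coexpressed_pairs`) as the true interaction
pairs, so any difference between true and null summaries reflects the
pair structure, not the pipeline. The paper-style single random draw is
one setting of ``n_draws``; the default draws several replicates to
expose the null variability.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from coexpair.errors import ConfigError
from coexpair.coexpr import CoexprConfig, PairCoexprResult, coexpressed_pairs
from coexpair.io import GenePairTable
from coexpair.profiles import ClusterProfile

logger = logging.getLogger(__name__)

GENE_UNIVERSES = ("all_genes", "expressed_genes")

# below this many candidate pairs we enumerate and sample exactly;
# above, we rejection-sample distinct pairs
_ENUMERATE_LIMIT = 500_000


@dataclass
class NullConfig:
    """Settings of the random-pair null."""

    n_pairs: int | None = None  # default: size of the true pair table
    n_draws: int = 25
    seed: int = 0
    exclude_true_pairs: bool = True
    gene_universe: str = "expressed_genes"

    def validate(self) -> None:
        if self.n_pairs is not None and self.n_pairs < 1:
            raise ConfigError(f"n_pairs must be >= 1, got {self.n_pairs}")
        if self.n_draws < 1:
            raise ConfigError(f"n_draws must be >= 1, got {self.n_draws}")
        if self.gene_universe not in GENE_UNIVERSES:
            raise ConfigError(
                f"gene_universe must be one of {GENE_UNIVERSES}, "
                f"got {self.gene_universe!r}"
            )


@dataclass
class NullSummary:
    """Per-cluster null r distribution and true-vs-null comparison."""

    clusters: list[str]
    #: cluster -> r of each replicate (NaN where undefined)
    r_replicates: dict[str, np.ndarray]
    n_replicates: dict[str, np.ndarray]
    table: pd.DataFrame
    #: cluster -> r_true - mean(r_null); present when a true result was given
    delta_r: dict[str, float] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False)
        return path


def draw_random_pairs(
    universe: list[str],
    true_pairs: GenePairTable | None,
    config: NullConfig,
) -> list[GenePairTable]:
    """Draw ``n_draws`` replicates of distinct unordered random pairs.

    Each replicate samples ``n_pairs`` unordered pairs uniformly without
    replacement from the universe, excluding self-pairs and (when
    configured) the true pairs; within-pair order is then randomized.
    Deterministic for a fixed seed.
    """
    config.validate()
    universe = list(dict.fromkeys(universe))
    n = len(universe)
    n_pairs = config.n_pairs
    if n_pairs is None:
        if true_pairs is None:
            raise ConfigError("n_pairs not set and no true pair table given")
        n_pairs = len(true_pairs)

    excluded: set[frozenset[str]] = set()
    if config.exclude_true_pairs and true_pairs is not None:
        excluded = {
            frozenset(p) for p in true_pairs.pairs if p[0] in universe and p[1] in universe
        }
    total = n * (n - 1) // 2 - len(excluded)
    if n_pairs > total:
        raise ConfigError(
            f"cannot draw {n_pairs} distinct pairs from a universe of {n} "
            f"genes with {len(excluded)} excluded pairs ({total} available)"
        )

    rng = np.random.default_rng(config.seed)
    replicates = []
    for d in range(config.n_draws):
        if n * (n - 1) // 2 <= _ENUMERATE_LIMIT:
            candidates = [
                (universe[i], universe[j])
                for i, j in itertools.combinations(range(n), 2)
                if frozenset((universe[i], universe[j])) not in excluded
            ]
            chosen_idx = rng.choice(len(candidates), size=n_pairs, replace=False)
            chosen = [candidates[i] for i in chosen_idx]
        else:
            seen: set[frozenset[str]] = set()
            chosen = []
            while len(chosen) < n_pairs:
                i, j = rng.integers(0, n, size=2)
                if i == j:
                    continue
                key = frozenset((universe[i], universe[j]))
                if key in seen or key in excluded:
                    continue
                seen.add(key)
                chosen.append((universe[i], universe[j]))
        flips = rng.random(n_pairs) < 0.5
        chosen = [
            (b, a) if flip else (a, b) for (a, b), flip in zip(chosen, flips)
        ]
        replicates.append(GenePairTable(pairs=chosen, source=f"null-draw-{d}"))
    return replicates


def expressed_gene_universe(profile: ClusterProfile) -> list[str]:
    """Genes with non-zero average expression in at least one cluster."""
    mask = (profile.avg > 0).any(axis=1)
    return [g for g, m in zip(profile.genes, mask) if m]


def null_coexpression(
    profile: ClusterProfile,
    replicates: list[GenePairTable],
    config: CoexprConfig | None = None,
    true_result: PairCoexprResult | None = None,
) -> NullSummary:
    """Run every replicate through the true-pair pipeline and summarize.

    The per-cluster summary reports mean/sd/min/max of r across the
    replicates with a defined r, plus the mean retained-pair count. When
    ``true_result`` is given, the comparison statistic
    ``delta_r = r_true - mean(r_null)`` is filled per cluster.
    """
    if not replicates:
        raise ConfigError("null_coexpression: no replicates")
    config = config or CoexprConfig()
    results = [coexpressed_pairs(profile, rep, config) for rep in replicates]

    clusters = list(profile.clusters)
    r_reps = {
        c: np.array([res.pearson_r[c] for res in results]) for c in clusters
    }
    n_reps = {
        c: np.array([res.n_coexpressed[c] for res in results]) for c in clusters
    }
    rows = []
    delta: dict[str, float] = {}
    for c in clusters:
        r = r_reps[c]
        defined = r[~np.isnan(r)]
        mean_r = float(np.mean(defined)) if defined.size else float("nan")
        row = {
            "cluster": c,
            "n_replicates": len(r),
            "mean_n_coexpressed": float(np.mean(n_reps[c])),
            "mean_r": mean_r,
            "sd_r": float(np.std(defined, ddof=1)) if defined.size > 1 else float("nan"),
            "min_r": float(np.min(defined)) if defined.size else float("nan"),
            "max_r": float(np.max(defined)) if defined.size else float("nan"),
        }
        if true_result is not None:
            r_true = true_result.pearson_r.get(c, float("nan"))
            d = r_true - mean_r
            row["r_true"] = r_true
            row["delta_r"] = d
            if not math.isnan(d):
                delta[c] = d
        rows.append(row)
    return NullSummary(
        clusters=clusters,
        r_replicates=r_reps,
        n_replicates=n_reps,
        table=pd.DataFrame(rows),
        delta_r=delta,
    )
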