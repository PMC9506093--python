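"""Synthetic clustered single-cell / single-nucleus UMI count generator.

The generator plants the structure the downstream analysis looks for:

* K clusters of entities, each with its own marker genes up-regulated by a
  configurable fold;
* designated gene pairs whose latent per-cell expression rates are
  correlated (target Pearson ``pair_rho``) within their active clusters,
  and whose per-cluster mean levels co-vary across clusters with the same
  correlation — so pair co-expression is visible both at the cell level
  and on the cluster-average scale;
* a negative-binomial observation model: per-cell gamma (background genes)
  or correlated lognormal (pair genes) rate noise, multinomial-like
  Poisson sampling at a modality-dependent sequencing depth.

Count-level pair correlation is depth-attenuated relative to ``pair_rho``;
the latent rates of the pair genes are therefore kept in the ground truth
(``pair_latent``) so the planted correlation can be estimated without
attenuation. The lognormal noise correlation is analytically corrected so
that the Pearson correlation of the latent rates equals ``pair_rho``
exactly in expectation.

One seed drives everything through a single ``SeedSequence``; per-cluster
sub-streams are spawned deterministically, so output is bit-identical for
identical (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from coexpair.errors import ConfigError
from coexpair.io import (
    ClusterAssignment,
    CountMatrix,
    GenePairTable,
    MarkerTable,
    write_10x,
    write_clusters,
    write_markers,
    write_pairs,
)

logger = logging.getLogger(__name__)

# Log-scale spread of background gene abundances; heavy-tailed enough that
# detection depends on depth, as in real UMI data.
_SIGMA_BASE = 1.5
# Elevation and spread of pair-gene cluster means (log scale).
_MU_PAIR = 1.5
_SIGMA_PAIR = 1.0
# Baseline log-mean of marker genes outside their home cluster.
_MU_MARKER = 0.5
# Log-sd of the per-cell latent noise on pair genes.
_SIGMA_CELL = 0.8
# Log-sd of per-entity depth jitter around the modality depth mean.
_SIGMA_DEPTH = 0.2


@dataclass
class SimConfig:
    """Configuration of one simulated library."""

    n_clusters: int = 5
    cells_per_cluster: int = 200
    n_genes: int = 1200
    n_pairs: int = 40
    pair_rho: float = 0.6
    markers_per_cluster: int = 3
    marker_fold: float = 8.0
    modality: str = "cell"
    depth_mean_cell: float = 5000.0
    depth_mean_nucleus: float = 800.0
    nb_dispersion: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        def bad(msg: str) -> ConfigError:
            return ConfigError(f"invalid SimConfig: {msg}")

        if self.n_clusters < 1:
            raise bad(f"n_clusters must be >= 1, got {self.n_clusters}")
        if self.cells_per_cluster < 1:
            raise bad(
                f"cells_per_cluster must be >= 1, got {self.cells_per_cluster}"
            )
        if self.n_genes < 1:
            raise bad(f"n_genes must be >= 1, got {self.n_genes}")
        if self.n_pairs < 0:
            raise bad(f"n_pairs must be >= 0, got {self.n_pairs}")
        if not 0.0 <= self.pair_rho <= 1.0:
            raise bad(f"pair_rho must be in [0, 1], got {self.pair_rho}")
        if self.markers_per_cluster < 0:
            raise bad(
                f"markers_per_cluster must be >= 0, got {self.markers_per_cluster}"
            )
        if self.marker_fold <= 1.0:
            raise bad(f"marker_fold must be > 1, got {self.marker_fold}")
        if self.modality not in ("cell", "nucleus"):
            raise bad(f"modality must be 'cell' or 'nucleus', got {self.modality!r}")
        if self.depth_mean_cell <= 0 or self.depth_mean_nucleus <= 0:
            raise bad("depth means must be > 0")
        if self.nb_dispersion <= 0:
            raise bad(f"nb_dispersion must be > 0, got {self.nb_dispersion}")
        reserved = 2 * self.n_pairs + self.markers_per_cluster * self.n_clusters
        if reserved > self.n_genes:
            raise bad(
                f"2*n_pairs + markers_per_cluster*n_clusters = {reserved} "
                f"exceeds n_genes = {self.n_genes}"
            )

    @property
    def depth_mean(self) -> float:
        return self.depth_mean_cell if self.modality == "cell" else self.depth_mean_nucleus


@dataclass
class GroundTruth:
    """Planted structure of a simulated library."""

    cluster_of: dict[str, str]
    true_pairs: list[tuple[str, str]]
    marker_map: dict[str, str]
    pair_active_clusters: dict[tuple[str, str], set[str]]
    #: latent per-entity rates of the pair genes, entities x (2*n_pairs);
    #: columns ordered (pair0.geneA, pair0.geneB, pair1.geneA, ...).
    pair_latent: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    pair_gene_columns: list[str] = field(default_factory=list)

    def latent_pair_correlation(
        self, matrix: CountMatrix, pair_index: int, cluster: str
    ) -> float:
        """Pearson r of a planted pair's latent rates within one cluster."""
        rows = [
            i
            for i, b in enumerate(matrix.barcodes)
            if self.cluster_of[b] == cluster
        ]
        x = self.pair_latent[rows, 2 * pair_index]
        y = self.pair_latent[rows, 2 * pair_index + 1]
        return float(np.corrcoef(x, y)[0, 1])


def _lognormal_rho(target_rho: float, sigma: float) -> float:
    """Log-scale correlation giving Pearson ``target_rho`` after exp().

    For equal log-sd ``sigma``, corr(exp(X), exp(Y)) =
    (exp(rho*sigma^2) - 1) / (exp(sigma^2) - 1); invert for rho.
    """
    if target_rho <= 0.0:
        return 0.0
    s2 = sigma * sigma
    return math.log1p(target_rho * math.expm1(s2)) / s2


def simulate(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw one library according to ``config``.

    Returns the sparse count matrix (entities x genes) and the planted
    ground truth. All pairs are active in all clusters.
    """
    import scipy.sparse as sp

    config.validate()
    K = config.n_clusters
    n_cells = config.cells_per_cluster
    G = config.n_genes
    P = config.n_pairs
    M = config.markers_per_cluster

    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(K + 1)
    rng = np.random.default_rng(child_seeds[0])  # gene-level draws

    gene_ids = [f"G{i:05d}" for i in range(G)]
    clusters = [f"C{k + 1}" for k in range(K)]

    perm = rng.permutation(G)
    pair_gene_idx = perm[: 2 * P]
    marker_idx = perm[2 * P : 2 * P + M * K].reshape(K, M) if M else np.empty(
        (K, 0), dtype=int
    )
    true_pairs = [
        (gene_ids[pair_gene_idx[2 * p]], gene_ids[pair_gene_idx[2 * p + 1]])
        for p in range(P)
    ]
    marker_map = {
        gene_ids[g]: clusters[k] for k in range(K) for g in marker_idx[k]
    }

    # log-mean matrix, genes x clusters
    log_mu = np.tile(rng.normal(0.0, _SIGMA_BASE, size=G)[:, None], (1, K))
    for k in range(K):
        log_mu[marker_idx[k], :] = _MU_MARKER
        log_mu[marker_idx[k], k] = _MU_MARKER + math.log(config.marker_fold)

    # pair-gene cluster means: bivariate with correlation pair_rho, split
    # half into a gene-level and half into a cluster-level component so the
    # correlation is visible both across clusters and across pairs.
    rho = config.pair_rho
    if P:
        cov = np.array([[1.0, rho], [rho, 1.0]])
        chol = np.linalg.cholesky(cov)
        g_lvl = rng.standard_normal((P, 2)) @ chol.T  # pair-level
        h_lvl = rng.standard_normal((P, K, 2)) @ chol.T  # pair x cluster
        x = math.sqrt(0.5) * g_lvl[:, None, :] + math.sqrt(0.5) * h_lvl
        for p in range(P):
            log_mu[pair_gene_idx[2 * p], :] = _MU_PAIR + _SIGMA_PAIR * x[p, :, 0]
            log_mu[pair_gene_idx[2 * p + 1], :] = _MU_PAIR + _SIGMA_PAIR * x[p, :, 1]
    mu = np.exp(log_mu)

    # per-cluster cell-level draws
    rho_log = _lognormal_rho(rho, _SIGMA_CELL)
    chol_cell = np.linalg.cholesky(
        np.array([[1.0, rho_log], [rho_log, 1.0]])
    )
    shape = 1.0 / config.nb_dispersion
    depth_mean = config.depth_mean

    blocks = []
    barcodes: list[str] = []
    cluster_of: dict[str, str] = {}
    pair_latent = np.empty((K * n_cells, 2 * P))
    bg_mask = np.ones(G, dtype=bool)
    bg_mask[pair_gene_idx] = False

    for k in range(K):
        crng = np.random.default_rng(child_seeds[k + 1])
        rates = np.empty((n_cells, G))
        # background + marker genes: gamma mixing -> NB marginal counts
        rates[:, bg_mask] = mu[bg_mask, k][None, :] * crng.gamma(
            shape, scale=config.nb_dispersion, size=(n_cells, int(bg_mask.sum()))
        )
        # pair genes: correlated lognormal noise, unit mean
        if P:
            e = crng.standard_normal((n_cells, P, 2)) @ chol_cell.T
            noise = np.exp(_SIGMA_CELL * e - 0.5 * _SIGMA_CELL**2)
            for p in range(P):
                ia, ib = pair_gene_idx[2 * p], pair_gene_idx[2 * p + 1]
                rates[:, ia] = mu[ia, k] * noise[:, p, 0]
                rates[:, ib] = mu[ib, k] * noise[:, p, 1]
                pair_latent[k * n_cells : (k + 1) * n_cells, 2 * p] = rates[:, ia]
                pair_latent[k * n_cells : (k + 1) * n_cells, 2 * p + 1] = rates[:, ib]

        depth = depth_mean * np.exp(
            _SIGMA_DEPTH * crng.standard_normal(n_cells) - 0.5 * _SIGMA_DEPTH**2
        )
        probs = rates / rates.sum(axis=1, keepdims=True)
        counts = crng.poisson(depth[:, None] * probs)
        blocks.append(sp.csr_matrix(counts))
        for j in range(n_cells):
            bc = f"BC{k * n_cells + j:06d}"
            barcodes.append(bc)
            cluster_of[bc] = clusters[k]

    matrix = CountMatrix(
        counts=sp.vstack(blocks).tocsr(),
        barcodes=barcodes,
        genes=gene_ids,
        modality=config.modality,
        library_id=f"sim-seed{config.seed}",
    )
    truth = GroundTruth(
        cluster_of=cluster_of,
        true_pairs=true_pairs,
        marker_map=marker_map,
        pair_active_clusters={pair: set(clusters) for pair in true_pairs},
        pair_latent=pair_latent,
        pair_gene_columns=[g for pair in true_pairs for g in pair],
    )
    logger.info(
        "simulated %d x %d matrix (%s modality, %d pairs, %d markers)",
        len(barcodes),
        G,
        config.modality,
        P,
        len(marker_map),
    )
    return matrix, truth


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture(
    matrix: CountMatrix, truth: GroundTruth, dir: str | Path
) -> dict:
    """Write a full fixture bundle and return its manifest.

    Emits matrix.mtx + barcodes.tsv + features.tsv + clusters.tsv +
    pairs.tsv + markers.tsv + manifest.json (file list with sha256).
    """
    dir = Path(dir)
    dir.mkdir(parents=True, exist_ok=True)
    paths = write_10x(matrix, dir)
    assignment = ClusterAssignment(labels=dict(truth.cluster_of))
    paths.append(write_clusters(assignment, dir / "clusters.tsv"))
    paths.append(
        write_pairs(GenePairTable(pairs=list(truth.true_pairs)), dir / "pairs.tsv")
    )
    paths.append(
        write_markers(
            MarkerTable(entries=list(truth.marker_map.items())),
            dir / "markers.tsv",
        )
    )
    manifest = {
        "modality": matrix.modality,
        "library_id": matrix.library_id,
        "n_barcodes": len(matrix.barcodes),
        "n_genes": len(matrix.genes),
        "total_count": matrix.total_count(),
        "files": {p.name: {"sha256": _sha256(p), "bytes": p.stat().st_size} for p in paths},
    }
    with open(dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
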