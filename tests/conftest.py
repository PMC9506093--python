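import numpy as np
import pytest
import scipy.sparse as sp

from coexpair.io import ClusterAssignment, CountMatrix, GenePairTable
from coexpair.simulate import SimConfig, simulate


def make_matrix(
    counts: np.ndarray,
    barcodes: list[str] | None = None,
    genes: list[str] | None = None,
    modality: str = "cell",
) -> CountMatrix:
    counts = np.asarray(counts)
    n_bc, n_g = counts.shape
    return CountMatrix(
        counts=sp.csr_matrix(counts),
        barcodes=barcodes or [f"BC{i:04d}" for i in range(n_bc)],
        genes=genes or [f"G{i:04d}" for i in range(n_g)],
        modality=modality,
    )


def random_matrix(
    rng: np.random.Generator, n_barcodes: int = 60, n_genes: int = 30
) -> CountMatrix:
    """Sparse-ish random count matrix for oracle tests."""
    dense = rng.poisson(rng.gamma(0.5, 4.0, size=(n_barcodes, n_genes)))
    return make_matrix(dense)


def random_assignment(
    rng: np.random.Generator, barcodes: list[str], n_clusters: int = 3
) -> ClusterAssignment:
    labels = {
        b: f"K{rng.integers(n_clusters)}" for b in barcodes
    }
    return ClusterAssignment(labels=labels)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated library + truth, shared across tests."""
    cfg = SimConfig(
        n_clusters=3,
        cells_per_cluster=80,
        n_genes=300,
        n_pairs=15,
        pair_rho=0.6,
        markers_per_cluster=3,
        marker_fold=10.0,
        seed=7,
    )
    matrix, truth = simulate(cfg)
    return cfg, matrix, truth


@pytest.fixture
def toy_pairs() -> GenePairTable:
    return GenePairTable(pairs=[("G0001", "G0002"), ("G0003", "G0004")])
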