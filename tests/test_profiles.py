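import numpy as np
import pytest
from scipy.cluster.vq import kmeans2

from coexpair.errors import DataError
from coexpair.io import ClusterAssignment, MarkerTable
from coexpair.profiles import (
    AnnotationEntry,
    ClusterAnnotation,
    annotate_clusters,
    average_by_cluster,
    dotplot_stats,
    normalize,
    transfer_labels,
)
from coexpair.simulate import SimConfig, simulate

from conftest import make_matrix, random_assignment, random_matrix


class TestNormalize:
    def test_already_at_scale(self):
        m = make_matrix(np.array([[1, 1, 2]]))
        norm = normalize(m, scale=4)
        np.testing.assert_allclose(
            np.expm1(np.asarray(norm.values.todense())[0]), [1, 1, 2]
        )

    def test_conservation(self, rng):
        m = random_matrix(rng, 30, 12)
        norm = normalize(m, scale=1e4)
        dense = np.expm1(np.asarray(norm.values.todense()))
        totals = np.asarray(m.counts.sum(axis=1)).ravel()
        for i in np.flatnonzero(totals > 0):
            assert dense[i].sum() == pytest.approx(1e4)

    def test_zero_total_barcode_stays_zero(self):
        m = make_matrix(np.array([[0, 0], [1, 1]]))
        norm = normalize(m)
        assert norm.values[0].nnz == 0

    def test_matches_dense_oracle(self, rng):
        m = random_matrix(rng, 40, 10)
        norm = normalize(m, scale=100.0)
        dense = np.asarray(m.counts.todense(), dtype=float)
        totals = dense.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            expected = np.log1p(np.where(totals > 0, dense / totals * 100.0, 0.0))
        np.testing.assert_allclose(
            np.asarray(norm.values.todense()), expected, atol=1e-12
        )


class TestAverageByCluster:
    def test_single_entity_cluster(self, rng):
        m = random_matrix(rng, 3, 5)
        asg = ClusterAssignment(
            labels={m.barcodes[0]: "solo", m.barcodes[1]: "duo", m.barcodes[2]: "duo"}
        )
        norm = normalize(m)
        prof = average_by_cluster(norm, asg)
        expected = np.expm1(np.asarray(norm.values[0].todense())).ravel()
        np.testing.assert_allclose(prof.avg[:, prof.clusters.index("solo")], expected)

    def test_identical_profiles_average_to_shared(self):
        row = np.array([2, 0, 4])
        m = make_matrix(np.vstack([row, row]))
        asg = ClusterAssignment(labels={b: "c" for b in m.barcodes})
        prof = average_by_cluster(normalize(m), asg)
        single = np.expm1(np.asarray(normalize(m).values[0].todense())).ravel()
        np.testing.assert_allclose(prof.avg[:, 0], single)

    def test_matches_dense_group_mean_oracle(self, rng):
        m = random_matrix(rng, 50, 20)
        asg = random_assignment(rng, m.barcodes, 3)
        norm = normalize(m)
        prof = average_by_cluster(norm, asg)
        dense = np.expm1(np.asarray(norm.values.todense()))
        for j, c in enumerate(prof.clusters):
            rows = [i for i, b in enumerate(m.barcodes) if asg.labels[b] == c]
            np.testing.assert_allclose(prof.avg[:, j], dense[rows].mean(axis=0))
        assert prof.n_entities == {
            c: sum(1 for b in m.barcodes if asg.labels[b] == c)
            for c in prof.clusters
        }

    def test_raw_average_mode(self, rng):
        m = random_matrix(rng, 20, 8)
        asg = random_assignment(rng, m.barcodes, 2)
        prof = average_by_cluster(m, asg)
        dense = np.asarray(m.counts.todense())
        for j, c in enumerate(prof.clusters):
            rows = [i for i, b in enumerate(m.barcodes) if asg.labels[b] == c]
            np.testing.assert_allclose(prof.avg[:, j], dense[rows].mean(axis=0))
        assert prof.norm_scale is None

    def test_all_zero_gene_stays_zero(self, rng):
        counts = np.asarray(random_matrix(rng, 15, 6).counts.todense())
        counts[:, 2] = 0
        m = make_matrix(counts)
        asg = random_assignment(rng, m.barcodes, 2)
        prof = average_by_cluster(normalize(m), asg)
        assert (prof.avg[2, :] == 0).all()

    def test_permutation_equivariance(self, rng):
        m = random_matrix(rng, 30, 8)
        asg = random_assignment(rng, m.barcodes, 3)
        renamed = ClusterAssignment(
            labels={b: "X" + c for b, c in asg.labels.items()}
        )
        p1 = average_by_cluster(normalize(m), asg)
        p2 = average_by_cluster(normalize(m), renamed)
        for c in p1.clusters:
            np.testing.assert_allclose(
                p1.avg[:, p1.clusters.index(c)],
                p2.avg[:, p2.clusters.index("X" + c)],
            )

    def test_subset_consistency(self, rng):
        # restricting to a gene subset leaves those genes' averages unchanged
        m = random_matrix(rng, 40, 12)
        asg = random_assignment(rng, m.barcodes, 3)
        full = average_by_cluster(m, asg)
        subset_genes = m.genes[3:8]
        sub = average_by_cluster(m.subset_genes(subset_genes), asg)
        for g in subset_genes:
            np.testing.assert_allclose(
                sub.avg[sub.gene_index()[g], :],
                full.avg[full.gene_index()[g], :],
            )

    def test_unmatched_cluster_dropped(self, rng):
        m = random_matrix(rng, 10, 5)
        labels = {b: "a" for b in m.barcodes}
        labels["ghost-barcode"] = "b"
        asg = ClusterAssignment(labels=labels)
        prof = average_by_cluster(normalize(m), asg)
        assert prof.clusters == ["a"]

    def test_no_matching_barcode_is_error(self, rng):
        m = random_matrix(rng, 5, 5)
        asg = ClusterAssignment(labels={"nope": "c"})
        with pytest.raises(DataError, match="no barcode"):
            average_by_cluster(normalize(m), asg)


class TestDotPlotStats:
    def test_absent_gene_zero(self):
        counts = np.array([[0, 3], [0, 1]])
        m = make_matrix(counts)
        asg = ClusterAssignment(labels={b: "c" for b in m.barcodes})
        stats = dotplot_stats(m, normalize(m), asg, m.genes)
        pct, mean = stats.get(m.genes[0], "c")
        assert pct == 0.0 and mean == 0.0

    def test_gene_in_every_entity_pct_100(self):
        counts = np.array([[1, 0], [5, 0], [2, 0]])
        m = make_matrix(counts)
        asg = ClusterAssignment(labels={b: "c" for b in m.barcodes})
        stats = dotplot_stats(m, normalize(m), asg, m.genes)
        pct, _ = stats.get(m.genes[0], "c")
        assert pct == 100.0

    def test_matches_brute_force(self, rng):
        m = random_matrix(rng, 40, 10)
        asg = random_assignment(rng, m.barcodes, 3)
        norm = normalize(m)
        stats = dotplot_stats(m, norm, asg, m.genes)
        dense_raw = np.asarray(m.counts.todense())
        dense_norm = np.asarray(norm.values.todense())
        gi = m.gene_index()
        for c in set(asg.labels.values()):
            rows = [i for i, b in enumerate(m.barcodes) if asg.labels[b] == c]
            for g in m.genes:
                pct, mean = stats.get(g, c)
                col = gi[g]
                assert pct == pytest.approx(
                    100.0 * (dense_raw[rows, col] > 0).mean()
                )
                assert mean == pytest.approx(dense_norm[rows, col].mean())

    def test_unknown_gene_reported(self, rng):
        m = random_matrix(rng, 10, 4)
        asg = ClusterAssignment(labels={b: "c" for b in m.barcodes})
        stats = dotplot_stats(m, normalize(m), asg, [m.genes[0], "NOPE"])
        assert stats.unknown_genes == ["NOPE"]
        assert set(stats.table["gene"]) == {m.genes[0]}


class TestAnnotateClusters:
    def _stats_for(self, matrix, truth):
        asg = ClusterAssignment(labels=dict(truth.cluster_of))
        norm = normalize(matrix)
        genes = list(truth.marker_map)
        return dotplot_stats(matrix, norm, asg, genes)

    def test_recovers_planted_markers(self, small_sim):
        _, matrix, truth = small_sim
        stats = self._stats_for(matrix, truth)
        markers = MarkerTable(entries=list(truth.marker_map.items()))
        annotation = annotate_clusters(stats, markers)
        # each cluster's label is the cluster itself (marker cell type ==
        # home cluster label in the simulator)
        for cluster, entry in annotation.entries.items():
            assert entry.label == cluster

    def test_single_cluster_single_type(self):
        counts = np.array([[5, 0], [4, 1]])
        m = make_matrix(counts)
        asg = ClusterAssignment(labels={b: "c" for b in m.barcodes})
        stats = dotplot_stats(m, normalize(m), asg, m.genes)
        annotation = annotate_clusters(
            stats, MarkerTable(entries=[(m.genes[0], "onlytype")])
        )
        assert annotation.label_of("c") == "onlytype"

    def test_tie_broken_lexicographically(self):
        # two cell types with identical marker statistics
        counts = np.array([[3, 3], [3, 3]])
        m = make_matrix(counts)
        asg = ClusterAssignment(labels={b: "c" for b in m.barcodes})
        stats = dotplot_stats(m, normalize(m), asg, m.genes)
        markers = MarkerTable(
            entries=[(m.genes[0], "zeta"), (m.genes[1], "alpha")]
        )
        annotation = annotate_clusters(stats, markers)
        assert annotation.label_of("c") == "alpha"

    def test_all_zero_panel_unassigned(self):
        counts = np.array([[0, 5], [0, 3]])
        m = make_matrix(counts)
        asg = ClusterAssignment(labels={b: "c" for b in m.barcodes})
        stats = dotplot_stats(m, normalize(m), asg, [m.genes[0]])
        annotation = annotate_clusters(
            stats, MarkerTable(entries=[(m.genes[0], "ghost")])
        )
        assert annotation.label_of("c") == "unassigned"


class TestTransferLabels:
    def _annotation(self, labels: dict[str, str]) -> ClusterAnnotation:
        return ClusterAnnotation(
            entries={
                c: AnnotationEntry(label, 1.0, []) for c, label in labels.items()
            }
        )

    def test_identity_transfer(self):
        asg = ClusterAssignment(
            labels={"b1": "c1", "b2": "c1", "b3": "c2"}
        )
        annot = self._annotation({"c1": "epidermis", "c2": "stele"})
        out = transfer_labels(asg, annot, asg)
        assert out.label_of("c1") == "epidermis"
        assert out.label_of("c2") == "stele"
        assert all(e.purity == 1.0 for e in out.entries.values())

    def test_even_split_tie(self):
        source = ClusterAssignment(labels={"b1": "s1", "b2": "s2"})
        annot = self._annotation({"s1": "beta", "s2": "alpha"})
        target = ClusterAssignment(labels={"b1": "t", "b2": "t"})
        out = transfer_labels(source, annot, target)
        assert out.label_of("t") == "alpha"  # lexicographic tie-break
        assert out.entries["t"].purity == 0.5

    def test_no_shared_barcode_cluster_unassigned(self):
        source = ClusterAssignment(labels={"b1": "s1"})
        annot = self._annotation({"s1": "alpha"})
        target = ClusterAssignment(labels={"b1": "t1", "zz": "t2"})
        out = transfer_labels(source, annot, target)
        assert out.label_of("t1") == "alpha"
        assert out.label_of("t2") == "unassigned"

    def test_disjoint_is_error(self):
        source = ClusterAssignment(labels={"b1": "s1"})
        annot = self._annotation({"s1": "alpha"})
        target = ClusterAssignment(labels={"x1": "t1"})
        with pytest.raises(DataError, match="share no barcode"):
            transfer_labels(source, annot, target)

    def test_reclustering_purity_monte_carlo(self):
        # re-cluster on the pair+marker gene subset via k-means; labels
        # transferred from ground truth should be mostly pure
        purities = []
        for seed in range(10):
            cfg = SimConfig(
                n_clusters=3,
                cells_per_cluster=60,
                n_genes=200,
                n_pairs=10,
                markers_per_cluster=4,
                marker_fold=12.0,
                seed=seed,
            )
            matrix, truth = simulate(cfg)
            subset = list(truth.marker_map) + [
                g for p in truth.true_pairs for g in p
            ]
            norm = normalize(matrix.subset_genes(subset))
            dense = np.asarray(norm.values.todense())
            _, labels = kmeans2(dense, cfg.n_clusters, seed=seed, minit="++")
            target = ClusterAssignment(
                labels={b: f"km{k}" for b, k in zip(matrix.barcodes, labels)}
            )
            source = ClusterAssignment(labels=dict(truth.cluster_of))
            annot = self._annotation(
                {c: c for c in source.cluster_ids}
            )
            out = transfer_labels(source, annot, target)
            for e in out.entries.values():
                if e.purity is not None and e.label != "unassigned":
                    purities.append(e.purity)
        assert np.median(purities) >= 0.9
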