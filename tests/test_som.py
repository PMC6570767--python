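"""The SOM classifier: scaling, training, node labeling, propagation, clustering."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from emtkit import (
    GeneratorConfig,
    HierarchicalBaseline,
    SOMClassifier,
    cluster_m_nodes,
    elbow_k,
    generate_expression_profiles,
    hclust_baseline,
    row_scale,
)
from emtkit.som import NodeLabeling, label_nodes


class TestRowScale:
    def test_simple_row_centred_and_unit_sd(self):
        out = row_scale([[1.0, 2.0, 3.0]])
        assert out.mean() == pytest.approx(0.0)
        assert out.std(ddof=1) == pytest.approx(1.0)

    def test_constant_row_becomes_zero_with_warning(self):
        with pytest.warns(RuntimeWarning):
            out = row_scale([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        assert np.allclose(out[0], 0.0)

    def test_idempotent(self, rng):
        x = rng.normal(size=(20, 8))
        once = row_scale(x)
        assert np.allclose(row_scale(once), once, atol=1e-12)


class TestTraining:
    def test_single_input_vector_attracts_codebooks(self):
        x = np.array([[1.0, -2.0, 0.5, 3.0]])
        som = SOMClassifier(
            n_rows=2, n_cols=2, n_epochs=300, scale_rows=False, random_state=0
        ).fit(x, ["M"])
        bmu_dist = np.linalg.norm(som.codebook_[som.assignment_[0]] - x[0])
        assert bmu_dist < 1e-3

    def test_separated_clouds_map_to_disjoint_nodes(self, rng):
        a = rng.normal(0.0, 0.1, (30, 4))
        b = rng.normal(5.0, 0.1, (30, 4))
        X = np.vstack([a, b])
        y = ["E"] * 30 + ["M"] * 30
        som = SOMClassifier(
            n_rows=2, n_cols=2, n_epochs=300, scale_rows=False, random_state=0
        ).fit(X, y)
        nodes_a = set(som.assignment_[:30])
        nodes_b = set(som.assignment_[30:])
        assert nodes_a.isdisjoint(nodes_b)

    def test_same_seed_identical_fit(self, rng):
        X = rng.normal(size=(40, 8))
        y = ["E"] * 20 + ["M"] * 20
        s1 = SOMClassifier(n_epochs=50, random_state=7).fit(X, y)
        s2 = SOMClassifier(n_epochs=50, random_state=7).fit(X, y)
        assert np.array_equal(s1.codebook_, s2.codebook_)
        assert np.array_equal(s1.assignment_, s2.assignment_)

    def test_quantization_error_decreases(self, fitted_som):
        assert fitted_som.quantization_error_ <= fitted_som.initial_quantization_error_

    def test_nan_input_rejected(self):
        X = np.full((3, 8), np.nan)
        with pytest.raises(ValueError):
            SOMClassifier().fit(X, ["E", "M", "E"])

    def test_sklearn_params_round_trip(self):
        som = SOMClassifier(n_epochs=5)
        params = som.get_params()
        assert params["n_epochs"] == 5
        som.set_params(n_rows=4)
        assert som.n_rows == 4


class TestNodeLabeling:
    def test_dominance_rule_cases(self):
        # three nodes: 4M/1E -> M, 1M/1E -> mixed, empty -> empty
        assignment = np.array([0] * 5 + [1] * 2)
        annotations = np.array(["M", "M", "M", "M", "E", "M", "E"], dtype=object)
        lab = label_nodes(assignment, annotations, n_nodes=3)
        assert list(lab.labels) == ["M", "mixed", "empty"]

    def test_exact_ratio_flagged(self):
        assignment = np.array([0, 0, 0])
        annotations = np.array(["M", "M", "E"], dtype=object)
        lab = label_nodes(assignment, annotations, n_nodes=1)
        assert lab.labels[0] == "M" and lab.at_ratio_boundary[0]

    def test_unannotated_genes_ignored_for_labeling(self):
        assignment = np.array([0, 0, 0, 0])
        annotations = np.array(["E", "none", "none", "none"], dtype=object)
        lab = label_nodes(assignment, annotations, n_nodes=1)
        assert lab.labels[0] == "E"

    def test_propagation_perfect_on_zero_noise_data(self, zero_noise_som):
        assert zero_noise_som.propagation_report_["correct_frac"] == 1.0
        assert zero_noise_som.propagation_report_["incorrect_frac"] == 0.0

    def test_zero_noise_em_calls_match_truth(self, zero_noise_som, zero_noise_dataset):
        emt = zero_noise_dataset.emt_subset()
        truth_em = np.where(emt.class_truth.to_numpy() == "E", "E", "M")
        assert np.mean(zero_noise_som.labels_ == truth_em) == 1.0


class TestElbow:
    def test_textbook_curve(self):
        assert elbow_k([100, 40, 20, 18, 17]) == 2

    def test_linear_decline_ties_to_smallest_k(self):
        assert elbow_k([50, 40, 30, 20, 10]) == 2

    def test_plateau_after_four(self):
        assert elbow_k([100, 80, 60, 40, 39.5, 39.2, 39.0]) == 4

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            elbow_k([10, 5])


class TestMClustering:
    def _dummy_som(self, codebooks, labels, assignment):
        som = SOMClassifier()
        som.codebook_ = np.asarray(codebooks, float)
        n = len(codebooks)
        som.node_labeling_ = NodeLabeling(
            labels=np.asarray(labels, object),
            e_counts=np.zeros(n, int),
            m_counts=np.zeros(n, int),
            n_genes=np.bincount(assignment, minlength=n),
            at_ratio_boundary=np.zeros(n, bool),
        )
        som.assignment_ = np.asarray(assignment)
        som.n_cols = n
        return som

    def test_distant_codebook_isolated_at_k2(self):
        # three M nodes at mutual distances 1, 1 and 10: complete linkage at
        # k=2 must isolate the far node
        som = self._dummy_som(
            [[0.0, 0.0], [1.0, 0.0], [10.0, 0.0]],
            ["M", "M", "M"],
            np.array([0, 0, 1, 1, 2]),
        )
        res = cluster_m_nodes(som, k=2, n_named=2)
        assert res.node_clusters[0] == res.node_clusters[1] != res.node_clusters[2]

    def test_identical_codebooks_tie_handled_deterministically(self):
        som = self._dummy_som(
            [[1.0, 1.0], [1.0, 1.0]], ["M", "M"], np.array([0, 1, 1])
        )
        r1 = cluster_m_nodes(som, k=2, n_named=2)
        r2 = cluster_m_nodes(som, k=2, n_named=2)
        assert r1.node_clusters == r2.node_clusters
        assert set(r1.node_clusters.values()) == {"M1", "M2"}

    def test_fewer_than_two_m_nodes_is_an_error(self):
        som = self._dummy_som([[0.0, 0.0]], ["M"], np.array([0]))
        with pytest.raises(ValueError):
            cluster_m_nodes(som)

    def test_zero_noise_m_subclusters_recovered_exactly(
        self, zero_noise_som, zero_noise_dataset
    ):
        emt = zero_noise_dataset.emt_subset()
        res = cluster_m_nodes(zero_noise_som, k=3)
        truth = emt.class_truth.to_numpy()
        m = np.isin(truth, ("M1", "M2", "M3"))
        assert adjusted_rand_score(truth[m], res.gene_clusters[m]) == 1.0

    def test_gene_clusters_partition_all_genes(self, fitted_som):
        res = cluster_m_nodes(fitted_som)
        assert res.gene_clusters.shape[0] == fitted_som.assignment_.shape[0]
        assert set(res.gene_clusters) <= {"M1", "M2", "M3", "other"}
        # WSS curve non-increasing in k
        assert np.all(np.diff(res.wss_curve) <= 1e-9)


class TestBaseline:
    def test_perfectly_separated_data_zero_error(self, rng):
        # classes differ in profile shape (row scaling removes mean offsets)
        e_tpl = np.array([1.0, -1.0] * 4)
        X = np.vstack(
            [e_tpl + rng.normal(0, 0.05, (15, 8)),
             -e_tpl + rng.normal(0, 0.05, (15, 8))]
        )
        y = ["E"] * 15 + ["M"] * 15
        _, rate = hclust_baseline(X, y)
        assert rate == 0.0

    def test_label_permutation_gives_same_partition_and_rate(self, rng):
        X = rng.normal(size=(30, 8))
        y = np.array(["E"] * 15 + ["M"] * 15, dtype=object)
        swapped = np.where(y == "E", "M", "E")
        e1 = HierarchicalBaseline().fit(X, y)
        e2 = HierarchicalBaseline().fit(X, swapped)
        assert np.array_equal(e1.partition_, e2.partition_)
        assert e1.misclassification_rate_ == e2.misclassification_rate_

    def test_som_not_worse_than_baseline_on_noisy_data(self):
        # higher-noise regime where the plain two-cluster cut starts failing
        cfg = GeneratorConfig(noise_sd=0.6, seed=3)
        emt = generate_expression_profiles(cfg).emt_subset()
        X, y = emt.logfc.to_numpy(), emt.annotation.to_numpy()
        som = SOMClassifier(random_state=3).fit(X, y)
        som_rate = som.propagation_report_["incorrect_frac"]
        _, base_rate = hclust_baseline(X, y)
        assert som_rate <= base_rate
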