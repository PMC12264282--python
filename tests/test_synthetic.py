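"""Synthetic benchmark generators: taxonomy, graph, shift, attack."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from icdgraph.graph import ValidationError
from icdgraph.synthetic import (SynthConfig, domain_shift,
                                generate_multilabel_graph, generate_taxonomy,
                                random_edge_attack)


class TestTaxonomy:
    def test_two_label_tree(self):
        parent, cooc = generate_taxonomy(2, 1, seed=0)
        assert parent[0] == -1 and parent[1] == 0
        assert cooc[0, 1] == pytest.approx(0.5)
        assert np.allclose(np.diag(cooc), 1.0)

    def test_deterministic_given_seed(self):
        p1, c1 = generate_taxonomy(15, 3, seed=7)
        p2, c2 = generate_taxonomy(15, 3, seed=7)
        assert np.array_equal(p1, p2)
        assert np.array_equal(c1, c2)

    def test_cooccurrence_decays_with_tree_distance(self):
        parent, cooc = generate_taxonomy(12, 3, seed=1)
        # recompute distances independently by walking parent pointers
        def ancestors(i):
            path = {i: 0}
            d = 0
            while parent[i] >= 0:
                i = parent[i]
                d += 1
                path[i] = d
            return path
        for i in range(12):
            ai = ancestors(i)
            for j in range(i + 1, 12):
                aj = ancestors(j)
                dist = min(ai[k] + aj[k] for k in set(ai) & set(aj))
                assert cooc[i, j] == pytest.approx(0.5**dist)

    def test_excessive_depth_rejected(self):
        with pytest.raises(ValidationError):
            generate_taxonomy(8, 6, seed=0)

    def test_symmetric(self):
        _, cooc = generate_taxonomy(10, 3, seed=2)
        assert np.array_equal(cooc, cooc.T)


class TestGraphGeneration:
    def test_counts_match_config_exactly(self):
        cfg = SynthConfig(n_nodes=200, avg_degree=6.0, seed=0)
        g = generate_multilabel_graph(cfg)
        assert g.n_nodes == 200
        assert g.n_edges == round(200 * 6.0 / 2)

    def test_deterministic_given_seed(self):
        cfg = SynthConfig(n_nodes=150, seed=5)
        g1 = generate_multilabel_graph(cfg)
        g2 = generate_multilabel_graph(SynthConfig(n_nodes=150, seed=5))
        assert np.array_equal(g1.features, g2.features)
        assert np.array_equal(g1.labels, g2.labels)
        assert (g1.adjacency != g2.adjacency).nnz == 0
        assert np.array_equal(g1.train_mask, g2.train_mask)

    def test_homophily_increases_with_h(self):
        def share_fraction(h):
            g = generate_multilabel_graph(SynthConfig(n_nodes=400, homophily=h, seed=3))
            Y = g.labels
            return np.mean([(Y[i] & Y[j]).sum() > 0 for i, j in g.edge_set()])
        assert share_fraction(0.9) > 0.7
        assert share_fraction(0.9) > share_fraction(0.3) > share_fraction(0.0)

    def test_h_zero_edges_independent_of_labels(self):
        g = generate_multilabel_graph(
            SynthConfig(n_nodes=2000, homophily=0.0, avg_degree=4.0, seed=1)
        )
        Y = g.labels
        iu, ju = np.triu_indices(g.n_nodes, k=1)
        share = (Y[iu] & Y[ju]).sum(axis=1) > 0
        A = g.adjacency.toarray().astype(bool)
        edge = A[iu, ju]
        table = np.array([
            [np.sum(edge & share), np.sum(edge & ~share)],
            [np.sum(~edge & share), np.sum(~edge & ~share)],
        ])
        _, p, _, _ = chi2_contingency(table)
        assert p > 0.01

    def test_masks_disjoint_and_sized(self):
        cfg = SynthConfig(n_nodes=200, labeled_fraction=0.1, val_fraction=0.15, seed=2)
        g = generate_multilabel_graph(cfg)
        assert len(g.train_mask) == 20
        assert len(g.val_mask) == 30
        assert len(g.test_mask) == 150
        assert not (set(g.train_mask) & set(g.val_mask) & set(g.test_mask))

    def test_zero_labeled_fraction_rejected(self):
        with pytest.raises(ValidationError):
            generate_multilabel_graph(SynthConfig(labeled_fraction=0.0))

    def test_counts_mode_produces_nonnegative_integers(self):
        g = generate_multilabel_graph(
            SynthConfig(n_nodes=100, feature_mode="counts", seed=0)
        )
        assert (g.features >= 0).all()
        assert np.array_equal(g.features, np.round(g.features))

    def test_single_label_mode_one_hot(self):
        g = generate_multilabel_graph(
            SynthConfig(n_nodes=100, labels_per_node=1.0, seed=0)
        )
        assert (g.labels.sum(axis=1) == 1).all()


class TestDomainShift:
    def test_zero_shift_is_identity(self):
        g = generate_multilabel_graph(SynthConfig(n_nodes=100, seed=0))
        twin = domain_shift(g, mean_shift=0.0, edge_rewire_rate=0.0, seed=1)
        assert np.array_equal(twin.features, g.features)
        assert (twin.adjacency != g.adjacency).nnz == 0

    def test_mean_shift_moves_empirical_mean(self):
        g = generate_multilabel_graph(SynthConfig(n_nodes=300, seed=1))
        twin = domain_shift(g, mean_shift=2.5, seed=2)
        delta = twin.features.mean() - g.features.mean()
        assert delta == pytest.approx(2.5, abs=1e-9)

    def test_rewire_changes_exact_count(self):
        g = generate_multilabel_graph(SynthConfig(n_nodes=200, avg_degree=6.0, seed=3))
        twin = domain_shift(g, edge_rewire_rate=0.1, seed=4)
        e0, e1 = g.edge_set(), twin.edge_set()
        k = round(0.1 * len(e0))
        assert len(e1) == len(e0)
        assert len(e0 - e1) == k  # removed
        assert len(e1 - e0) == k  # freshly added
        assert np.array_equal(twin.labels, g.labels)

    def test_variance_rescale(self):
        g = generate_multilabel_graph(SynthConfig(n_nodes=200, seed=5))
        twin = domain_shift(g, var_scale=2.0, seed=6)
        assert np.allclose(twin.features, g.features * 2.0)


class TestRandomEdgeAttack:
    def test_zero_rate_identity(self):
        g = generate_multilabel_graph(SynthConfig(n_nodes=100, seed=0))
        out = random_edge_attack(g, 0.0, seed=1)
        assert (out.adjacency != g.adjacency).nnz == 0

    def test_exact_edge_count(self):
        g = generate_multilabel_graph(SynthConfig(n_nodes=100, avg_degree=2.0, seed=1))
        assert g.n_edges == 100
        out = random_edge_attack(g, 0.1, seed=2)
        assert out.n_edges == 110

    def test_added_edges_disjoint_from_original(self):
        g = generate_multilabel_graph(SynthConfig(n_nodes=100, seed=2))
        out = random_edge_attack(g, 0.2, seed=3)
        assert g.edge_set() <= out.edge_set()

    def test_bad_rate_rejected(self):
        g = generate_multilabel_graph(SynthConfig(n_nodes=50, seed=0))
        with pytest.raises(ValidationError):
            random_edge_attack(g, 1.5)

    def test_deterministic(self):
        g = generate_multilabel_graph(SynthConfig(n_nodes=100, seed=4))
        a1 = random_edge_attack(g, 0.1, seed=9)
        a2 = random_edge_attack(g, 0.1, seed=9)
        assert (a1.adjacency != a2.adjacency).nnz == 0
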