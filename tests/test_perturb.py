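"""DropNode/dropout perturbation and the closed-form variance oracles."""

import numpy as np
import pytest

from icdgraph.graph import ValidationError, build_operator
from icdgraph.perturb import (analytic_variance_dropnode,
                              analytic_variance_dropout, dropnode,
                              dropout_elements, random_propagate,
                              regularizer_dropnode)

from conftest import make_graph, two_node_bar_op


def _find_seed(predicate, limit=200):
    for seed in range(limit):
        if predicate(seed):
            return seed
    raise AssertionError("no seed found with the requested mask pattern")


class TestDropNode:
    def test_delta_zero_is_identity(self):
        X = np.arange(6.0).reshape(3, 2)
        assert np.array_equal(dropnode(X, 0.0, 0), X)

    def test_survivors_rescaled(self):
        # delta=0.5: kept rows doubled, dropped rows zero
        X = np.array([[2.0], [4.0]])
        seed = _find_seed(
            lambda s: dropnode(X, 0.5, s)[0, 0] != 0 and dropnode(X, 0.5, s)[1, 0] == 0
        )
        assert np.array_equal(dropnode(X, 0.5, seed), [[4.0], [0.0]])

    def test_rows_all_or_nothing(self):
        X = np.random.default_rng(0).normal(size=(30, 4))
        out = dropnode(X, 0.3, 7)
        for i in range(30):
            assert np.allclose(out[i], 0) or np.allclose(out[i], X[i] / 0.7)

    def test_monte_carlo_mean_recovers_x(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 3))
        draws = np.mean([dropnode(X, 0.2, s) for s in range(3000)], axis=0)
        # per-element SE = |X| * sqrt(delta/(1-delta)) / sqrt(n_draws)
        se = np.abs(X) * np.sqrt(0.2 / 0.8) / np.sqrt(3000)
        assert (np.abs(draws - X) <= 4 * se + 1e-3).all()

    def test_delta_one_rejected(self):
        with pytest.raises(ValidationError):
            dropnode(np.zeros((2, 2)), 1.0, 0)


class TestDropoutElements:
    def test_delta_zero_is_identity(self):
        X = np.arange(4.0).reshape(2, 2)
        assert np.array_equal(dropout_elements(X, 0.0, 0), X)

    def test_elementwise_mask_and_scale(self):
        X = np.array([[1.0, 1.0]])
        seed = _find_seed(
            lambda s: dropout_elements(X, 0.5, s)[0, 0] == 0
            and dropout_elements(X, 0.5, s)[0, 1] != 0
        )
        assert np.array_equal(dropout_elements(X, 0.5, seed), [[0.0, 2.0]])

    def test_monte_carlo_mean_recovers_x(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 4))
        draws = np.mean([dropout_elements(X, 0.3, s) for s in range(3000)], axis=0)
        se = np.abs(X) * np.sqrt(0.3 / 0.7) / np.sqrt(3000)
        assert (np.abs(draws - X) <= 4 * se + 1e-3).all()


class TestRandomPropagate:
    def test_no_noise_all_identical(self, er_graph):
        op = build_operator(er_graph, "M2", 3)
        batch = random_propagate(er_graph, op, S=3, delta=0.0, seed=0)
        expected = op.apply_bar(er_graph.features)
        for Xb in batch.X_bar_list:
            assert np.allclose(Xb, expected)

    def test_worked_two_node_case(self, pair_graph):
        op = two_node_bar_op()
        pair_graph.features = np.array([[1.0], [1.0]])
        # find a seed whose single augmentation drops node 1 only
        for seed in range(200):
            b = random_propagate(pair_graph, op, S=1, delta=0.5, seed=seed)
            if np.allclose(b.X_tilde_list[0], [[2.0], [0.0]]):
                assert np.allclose(b.X_bar_list[0], [[1.5], [0.5]])
                return
        raise AssertionError("mask pattern not found")

    def test_deterministic_given_seed(self, er_graph):
        op = build_operator(er_graph, "M2", 2)
        b1 = random_propagate(er_graph, op, S=4, delta=0.3, seed=11)
        b2 = random_propagate(er_graph, op, S=4, delta=0.3, seed=11)
        for a, b in zip(b1.X_bar_list, b2.X_bar_list):
            assert np.array_equal(a, b)

    def test_augmentations_differ(self, er_graph):
        op = build_operator(er_graph, "M2", 2)
        b = random_propagate(er_graph, op, S=2, delta=0.3, seed=1)
        assert not np.allclose(b.X_tilde_list[0], b.X_tilde_list[1])

    def test_topology_untouched(self, er_graph):
        op = build_operator(er_graph, "M2", 2)
        before = er_graph.adjacency.toarray().copy()
        random_propagate(er_graph, op, S=3, delta=0.5, seed=0)
        assert np.array_equal(er_graph.adjacency.toarray(), before)

    def test_bad_mode_rejected(self, er_graph):
        op = build_operator(er_graph, "M2", 2)
        with pytest.raises(ValidationError):
            random_propagate(er_graph, op, S=1, delta=0.1, mode="dropedge")


class TestVarianceOracles:
    def test_delta_zero_gives_zeros(self):
        op = two_node_bar_op()
        X = np.ones((2, 1))
        assert np.allclose(analytic_variance_dropnode(op, X, [1.0], 0.0), 0)
        assert np.allclose(analytic_variance_dropout(op, X, [1.0], 0.0), 0)

    def test_two_node_worked_value(self):
        # Var_0 = (0.5/0.5) * ((0.75)^2 + (0.25)^2) * (x W)^2 = 0.625
        op = two_node_bar_op()
        var = analytic_variance_dropnode(op, np.ones((2, 1)), [1.0], 0.5)
        assert var[0] == pytest.approx(0.625)
        assert var[1] == pytest.approx(0.625)

    def test_row_vs_element_mask_differ(self, single_node):
        # single node, X = [[1, 1]], W = [1, 1]: row mask variance uses
        # (x.W)^2 = 4, element mask uses sum_f (x_f W_f)^2 = 2
        op = build_operator(single_node, "M2", 0)
        X = np.array([[1.0, 1.0]])
        W = np.array([1.0, 1.0])
        assert analytic_variance_dropnode(op, X, W, 0.5)[0] == pytest.approx(4.0)
        assert analytic_variance_dropout(op, X, W, 0.5)[0] == pytest.approx(2.0)

    @pytest.mark.parametrize("mode", ["dropnode", "dropout"])
    def test_matches_monte_carlo(self, mode, er_graph):
        op = build_operator(er_graph, "M2", 2)
        rng = np.random.default_rng(9)
        X = er_graph.features
        W = rng.normal(size=X.shape[1])
        delta, n_draws = 0.2, 20_000
        A_bar = op.A_bar
        if mode == "dropnode":
            keep = rng.random((n_draws, X.shape[0])) >= delta
            vals = (keep * (X @ W)[None, :] / (1 - delta)) @ A_bar.T
            analytic = analytic_variance_dropnode(op, X, W, delta)
        else:
            keep = rng.random((n_draws, X.shape[0], X.shape[1])) >= delta
            vals = ((keep * X[None] / (1 - delta)) @ W) @ A_bar.T
            analytic = analytic_variance_dropout(op, X, W, delta)
        mc = vals.var(axis=0, ddof=1)
        assert np.linalg.norm(mc - analytic) / np.linalg.norm(analytic) < 0.05


class TestRegularizer:
    def test_confident_predictions_give_zero(self):
        op = two_node_bar_op()
        X = np.ones((2, 1))
        assert regularizer_dropnode(op, X, [1.0], [0.0, 1.0], 0.5) == pytest.approx(0.0)

    def test_uncertainty_weight_peaks_at_half(self):
        z = np.linspace(0, 1, 101)
        w = z**2 * (1 - z) ** 2
        assert z[np.argmax(w)] == pytest.approx(0.5)
        assert w.max() == pytest.approx(0.0625)

    def test_two_node_worked_value(self):
        # sum_i 0.0625 * Var_i = 2 * 0.0625 * 0.625
        op = two_node_bar_op()
        val = regularizer_dropnode(op, np.ones((2, 1)), [1.0], [0.5, 0.5], 0.5)
        assert val == pytest.approx(2 * 0.0625 * 0.625)

    def test_invalid_z_rejected(self):
        op = two_node_bar_op()
        with pytest.raises(ValidationError):
            regularizer_dropnode(op, np.ones((2, 1)), [1.0], [1.5, 0.0], 0.5)
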