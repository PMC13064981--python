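import copy

import numpy as np
import pytest

from grnas.exceptions import ConfigurationError, ContractError
from grnas.model import (
    ArchitectureChoice,
    SearchSpace,
    endpoint_pool,
    graph_arrays,
    init_model_params,
    init_node_features,
    inter_layer_connect,
    intra_layer_forward,
    layer_aggregate,
    model_forward,
    score_link,
    scorer_input_width,
)
from oracles import forward_oracle, random_architecture, random_graph_instance, sigmoid


def _identity_layer(d):
    return {
        "W_self": np.eye(d),
        "W_nb": np.eye(d),
        "W_comb": np.vstack([np.eye(d), np.eye(d)]),
        "W_cnt": np.vstack([np.eye(d), np.zeros((d, d))]),
        "prelu": np.array(0.25),
    }


class TestInitNodeFeatures:
    def test_identity_projection_returns_raw_profiles(self, rng):
        X = rng.random((5, 3))
        h0 = init_node_features(X, {"W": np.eye(3), "b": np.zeros(3)})
        assert np.allclose(h0, X)

    def test_identical_profiles_get_identical_embeddings(self, rng):
        X = np.vstack([np.ones(4), np.ones(4), rng.random(4)])
        W = rng.standard_normal((4, 2))
        h0 = init_node_features(X, {"W": W, "b": np.zeros(2)})
        assert np.allclose(h0[0], h0[1])

    def test_seeded_init_reproducible(self):
        p1 = init_model_params(np.random.default_rng(3), 10, 4, 2, 4)
        p2 = init_model_params(np.random.default_rng(3), 10, 4, 2, 4)
        assert np.array_equal(p1["proj"]["W"], p2["proj"]["W"])

    def test_nonpositive_hidden_size_rejected(self):
        with pytest.raises(ConfigurationError):
            init_model_params(np.random.default_rng(0), 10, 0, 2, 4)


class TestIntraLayer:
    def test_hand_worked_two_node_example(self):
        # u -> v, identity weights, sum aggregation + sum combine + relu
        arrays = graph_arrays(
            np.zeros((2, 2)), np.array([[0, 1]]), 2, direction="directed", standardize=False
        )
        H = np.array([[1.0, -2.0], [0.5, 1.0]])
        out = intra_layer_forward(H, arrays, _identity_layer(2), "sum", "sum", "relu")
        assert np.allclose(out[1], [1.5, 0.0])
        assert np.allclose(out[0], [1.0, 0.0])  # empty neighborhood: T = 0

    def test_isolated_node_unchanged_under_identity(self):
        arrays = graph_arrays(np.zeros((1, 2)), np.zeros((0, 2)), 1, standardize=False)
        out = intra_layer_forward(
            np.array([[1.0, 1.0]]), arrays, _identity_layer(2), "sum", "sum", "relu"
        )
        assert np.allclose(out, [[1.0, 1.0]])

    @pytest.mark.parametrize("agg", ["mean", "sum", "max"])
    @pytest.mark.parametrize("combine", ["sum", "concat"])
    def test_matches_per_node_oracle(self, rng, agg, combine):
        from oracles import intra_oracle

        for _ in range(10):
            n, edges, X = random_graph_instance(rng, n_max=15, n_feat=4)
            arrays = graph_arrays(X, edges, n, direction="symmetric", standardize=False)
            d = 4
            lp = {
                "W_self": rng.standard_normal((d, d)),
                "W_nb": rng.standard_normal((d, d)),
                "W_comb": rng.standard_normal((2 * d, d)),
                "W_cnt": rng.standard_normal((2 * d, d)),
                "prelu": np.array(0.25),
            }
            H = rng.standard_normal((n, d))
            got = intra_layer_forward(H, arrays, lp, agg, combine, "prelu")
            want = intra_oracle(H, arrays["A"], lp, agg, combine, "prelu")
            assert np.allclose(got, want, atol=1e-6)


class TestInterLayerConnect:
    def test_stack_returns_intra_output_exactly(self, rng):
        a, b = rng.random((4, 3)), rng.random((4, 3))
        assert inter_layer_connect(a, b, "stack") is b

    def test_skip_sum_with_zero_previous_equals_stack(self, rng):
        b = rng.random((4, 3))
        assert np.allclose(inter_layer_connect(np.zeros_like(b), b, "skip_sum"), b)

    def test_skip_concat_block_projection_identity(self, rng):
        a, b = rng.random((4, 3)), rng.random((4, 3))
        w_cnt = np.vstack([np.eye(3), np.zeros((3, 3))])
        assert np.allclose(inter_layer_connect(a, b, "skip_concat", w_cnt), a)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ContractError):
            inter_layer_connect(rng.random((4, 3)), rng.random((5, 3)), "skip_sum")


class TestLayerAggregate:
    def test_skip_takes_last(self, rng):
        a, b = rng.random((4, 3)), rng.random((4, 3))
        assert layer_aggregate([a, b], "skip") is b

    def test_max_idempotent_on_identical_inputs(self, rng):
        a = rng.random((4, 3))
        assert np.allclose(layer_aggregate([a, a.copy()], "max"), a)

    def test_concat_widths_and_order(self, rng):
        a, b = rng.random((4, 3)), rng.random((4, 3))
        got = layer_aggregate([a, b], "concat")
        assert got.shape == (4, 6)
        assert np.allclose(got[:, :3], a)
        assert np.allclose(got[:, 3:], b)

    def test_empty_list_rejected(self):
        with pytest.raises(ContractError):
            layer_aggregate([], "skip")


class TestEndpointPool:
    def test_sum_max_closed_forms(self):
        u, v = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        assert np.allclose(endpoint_pool(u, v, "sum"), [4.0, 6.0])
        assert np.allclose(endpoint_pool(u, v, "max"), [3.0, 4.0])

    def test_concat_is_direction_aware(self):
        u, v = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        uv = endpoint_pool(u, v, "concat")
        vu = endpoint_pool(v, u, "concat")
        assert np.allclose(uv, [1, 2, 3, 4])
        assert np.allclose(vu, [3, 4, 1, 2])
        assert not np.allclose(uv, vu)

    def test_width_mismatch_raises(self):
        with pytest.raises(ContractError):
            endpoint_pool(np.ones(2), np.ones(3), "sum")


class TestScoreLink:
    def test_zero_scorer_outputs_half(self):
        sc = {"W1": np.zeros((4, 3)), "b1": np.zeros(3), "W2": np.zeros((3, 1)), "b2": np.zeros(1)}
        assert np.allclose(score_link(np.ones((2, 4)), sc), 0.5)

    def test_large_logit_saturates(self):
        sc = {"W1": np.eye(1), "b1": np.zeros(1), "W2": np.array([[1.0]]), "b2": np.zeros(1)}
        assert score_link(np.array([[20.0]]), sc)[0] > 0.999999

    def test_matches_affine_relu_affine_sigmoid(self, rng):
        sc = {
            "W1": rng.standard_normal((5, 4)),
            "b1": rng.standard_normal(4),
            "W2": rng.standard_normal((4, 1)),
            "b2": rng.standard_normal(1),
        }
        e = rng.standard_normal((7, 5))
        want = sigmoid(np.maximum(e @ sc["W1"] + sc["b1"], 0) @ sc["W2"] + sc["b2"]).ravel()
        assert np.allclose(score_link(e, sc), want, atol=1e-7)


class TestModelForward:
    def _setup(self, rng, choice, n_max=12):
        n, edges, X = random_graph_instance(rng, n_max=n_max)
        arrays = graph_arrays(X, edges, n, standardize=False)
        d = 4
        params = init_model_params(
            rng, X.shape[1], d, choice.n_layers, scorer_input_width(choice, d)
        )
        params["scorer"]["W2"] = rng.standard_normal((d, 1))  # avoid all-0.5 outputs
        pairs = np.column_stack([rng.integers(0, n, 6), rng.integers(0, n, 6)])
        return n, arrays, params, pairs

    def test_permutation_equivariance(self, rng):
        for _ in range(5):
            choice = random_architecture(rng, SearchSpace())
            n, edges, X = random_graph_instance(rng)
            d = 4
            params = init_model_params(
                rng, X.shape[1], d, 2, scorer_input_width(choice, d)
            )
            params["scorer"]["W2"] = rng.standard_normal((d, 1))
            pairs = np.column_stack([rng.integers(0, n, 5), rng.integers(0, n, 5)])
            arrays = graph_arrays(X, edges, n, standardize=False)
            base = np.asarray(model_forward(params, arrays, pairs, choice))

            perm = rng.permutation(n)
            inv = np.argsort(perm)
            arrays_p = graph_arrays(X[perm], inv[edges], n, standardize=False)
            got = np.asarray(model_forward(params, arrays_p, inv[pairs], choice))
            assert np.allclose(base, got, atol=1e-6)

    def test_empty_pairs_give_empty_output(self, rng):
        choice = ArchitectureChoice()
        n, arrays, params, _ = self._setup(rng, choice)
        out = model_forward(params, arrays, np.zeros((0, 2), dtype=int), choice)
        assert len(out) == 0

    def test_duplicate_pairs_score_identically(self, rng):
        choice = ArchitectureChoice()
        n, arrays, params, pairs = self._setup(rng, choice)
        doubled = np.vstack([pairs, pairs[:1]])
        out = np.asarray(model_forward(params, arrays, doubled, choice))
        assert out[-1] == out[0]

    def test_inputs_not_mutated(self, rng):
        choice = random_architecture(rng, SearchSpace())
        n, arrays, params, pairs = self._setup(rng, choice)
        params_before = copy.deepcopy(params)
        arrays_before = {k: copy.deepcopy(v) for k, v in arrays.items()}
        model_forward(params, arrays, pairs, choice)
        assert np.array_equal(params["proj"]["W"], params_before["proj"]["W"])
        assert np.array_equal(arrays["X"], arrays_before["X"])
        assert np.array_equal(arrays["A"], arrays_before["A"])

    def test_matches_loop_oracle_on_random_architectures(self, rng):
        for _ in range(25):
            choice = random_architecture(rng, SearchSpace())
            n, arrays, params, pairs = self._setup(rng, choice)
            got = np.asarray(model_forward(params, arrays, pairs, choice))
            want = forward_oracle(params, arrays["X"], arrays["A"], pairs, choice)
            assert np.allclose(got, want, atol=1e-6)


class TestArchitectureReport:
    def test_report_schema(self):
        report = ArchitectureChoice().to_report()
        assert set(report) == {"Agg", "Combine", "Activation", "LayerConnect", "LayerAgg", "Pool"}
        assert len(report["Agg"]) == 2

    def test_validate_rejects_foreign_operator(self):
        space = SearchSpace(intra_agg=("sum",))
        with pytest.raises(ConfigurationError):
            ArchitectureChoice(agg=("max", "max")).validate(space)

    def test_search_space_exhaustive_enumeration(self):
        archs = list(SearchSpace().architectures(2))
        assert len(archs) == 3 * 2 * 2 * 3 * 3 * 3
        assert len(set(archs)) == len(archs)
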