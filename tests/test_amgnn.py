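"""Graph operations, forward-pass invariants and meta-training behavior."""

import numpy as np
import pytest

from copdstage import (
    AMGNNConfig,
    AMGNNResults,
    AutoMetricGNN,
    CohortSpec,
    build_combination,
    generate_cohort,
    sample_episode,
    standardize,
)
from copdstage.amgnn import (
    DegenerateGraphError,
    Episode,
    EpisodeError,
    adjacency,
    edge_constraint_matrix,
    edge_weight_matrix,
    forward,
    layer_forward,
)


def _metric_params(rng, d, h):
    return {
        "W1": rng.normal(size=(d, h)),
        "b1": rng.normal(size=(h,)),
        "W2": rng.normal(size=(h, 1)),
        "b2": rng.normal(size=(1,)),
    }


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestSampleEpisode:
    def test_4way_10shot_has_40_support_nodes(self, small_pipeline):
        ep = sample_episode(
            small_pipeline["X_train"], small_pipeline["y_train"], small_pipeline["combo"],
            n_way=4, k_shot=10, rng=0,
        )
        assert ep.n_support == 40
        assert ep.n_query == 1
        counts = np.bincount(ep.support_labels, minlength=4)
        assert (counts == 10).all()

    def test_insufficient_class_raises_naming_it(self, small_pipeline):
        with pytest.raises(EpisodeError, match="stage 0"):
            sample_episode(
                small_pipeline["X_train"], small_pipeline["y_train"], small_pipeline["combo"],
                n_way=4, k_shot=50, rng=0,
            )

    def test_same_seed_same_episode(self, small_pipeline):
        args = (small_pipeline["X_train"], small_pipeline["y_train"], small_pipeline["combo"])
        e1 = sample_episode(*args, n_way=4, k_shot=5, rng=7)
        e2 = sample_episode(*args, n_way=4, k_shot=5, rng=7)
        assert e1.support_ids == e2.support_ids and e1.query_ids == e2.query_ids

    def test_support_query_disjoint(self, small_pipeline):
        ep = sample_episode(
            small_pipeline["X_train"], small_pipeline["y_train"], small_pipeline["combo"],
            n_way=4, k_shot=5, n_query=3, rng=3,
        )
        assert not set(ep.support_ids) & set(ep.query_ids)


class TestEdgeWeightMatrix:
    def test_symmetric_and_identical_nodes_share_weight(self, rng):
        V = rng.normal(size=(6, 5))
        V[3] = V[0]  # duplicated node
        params = _metric_params(rng, 5, 4)
        W = edge_weight_matrix(V, params)
        assert np.array_equal(W, W.T)
        # zero-difference pairs all equal sigma(f(0)): diagonal and the clone pair
        assert np.isclose(W[0, 3], W[0, 0], atol=1e-12)
        assert np.allclose(np.diag(W), W[0, 0], atol=1e-12)

    def test_frozen_channel_sum_gives_squashed_manhattan(self, rng):
        V = rng.normal(size=(5, 3))
        params = {"W1": np.ones((3, 1)), "b1": np.zeros(1), "W2": np.ones((1, 1)), "b2": np.zeros(1)}
        W = edge_weight_matrix(V, params)
        manhattan = np.abs(V[:, None, :] - V[None, :, :]).sum(axis=-1)
        # channel-sum is nonnegative, so the LeakyReLU stage is the identity here
        assert np.allclose(W, _sigmoid(manhattan), atol=1e-12)

    def test_values_in_unit_interval(self, rng):
        W = edge_weight_matrix(rng.normal(size=(7, 4)), _metric_params(rng, 4, 3))
        assert (W > 0).all() and (W < 1).all()

    def test_non_finite_rejected(self, rng):
        V = rng.normal(size=(4, 3))
        V[1, 1] = np.nan
        with pytest.raises(ValueError):
            edge_weight_matrix(V, _metric_params(rng, 3, 2))


class TestEdgeConstraintMatrix:
    def test_identical_risk_rows_give_all_ones(self):
        R = np.tile([0.3, -1.2], (5, 1))
        assert np.array_equal(edge_constraint_matrix(R, 1.0), np.ones((5, 5)))

    def test_unit_diagonal_exact(self, rng):
        E = edge_constraint_matrix(rng.normal(size=(6, 3)), 0.7)
        assert np.array_equal(np.diag(E), np.ones(6))
        assert np.array_equal(E, E.T)

    def test_closed_form_two_nodes(self):
        E = edge_constraint_matrix(np.array([[0.0], [1.0]]), 1.0)
        assert np.isclose(E[0, 1], np.exp(-1.0), atol=1e-12)

    def test_product_over_factors(self, rng):
        R = rng.normal(size=(4, 3))
        tau = np.array([0.5, 1.0, 2.0])
        E = edge_constraint_matrix(R, tau)
        manual = np.ones((4, 4))
        for k in range(3):
            d = R[:, k, None] - R[None, :, k]
            manual *= np.exp(-(d**2) / tau[k])
        assert np.allclose(E, manual, atol=1e-12)

    def test_nonpositive_bandwidth_rejected(self, rng):
        with pytest.raises(ValueError):
            edge_constraint_matrix(rng.normal(size=(3, 2)), 0.0)


class TestAdjacency:
    def test_rows_sum_to_one(self, rng):
        W = _sigmoid(rng.normal(size=(5, 5)))
        W = (W + W.T) / 2
        E = edge_constraint_matrix(rng.normal(size=(5, 2)), 1.0)
        A = adjacency(W, E)
        assert np.abs(A.sum(axis=-1) - 1.0).max() < 1e-10

    def test_all_ones_constraint_is_row_normalized_w(self, rng):
        W = _sigmoid(rng.normal(size=(4, 4)))
        A = adjacency(W, np.ones((4, 4)))
        assert np.allclose(A, W / W.sum(axis=-1, keepdims=True), atol=1e-12)

    def test_elementwise_quotient_oracle(self, rng):
        W = _sigmoid(rng.normal(size=(5, 5)))
        E = np.exp(-np.abs(rng.normal(size=(5, 5))))
        A = adjacency(W, E)
        M = W * E
        for i in range(5):
            for j in range(5):
                assert np.isclose(A[i, j], M[i, j] / M[i].sum(), atol=1e-12)

    def test_zero_row_degenerate(self):
        W = np.ones((3, 3))
        E = np.ones((3, 3))
        E[1, :] = 0.0
        with pytest.raises(DegenerateGraphError):
            adjacency(W, E)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            adjacency(np.ones((3, 3)), np.ones((4, 4)))


class TestLayerForward:
    def test_concat_width_contract(self, rng):
        V = rng.normal(size=(6, 5))
        A = np.full((6, 6), 1 / 6)
        params = {"W": rng.normal(size=(5, 8)), "b": rng.normal(size=(8,))}
        out = layer_forward(V, A, params)
        assert out.shape == (6, 5 + 8)

    def test_single_node_identity_layer(self):
        v = np.array([[1.5, -2.0]])
        params = {"W": np.eye(2), "b": np.zeros(2)}
        out = layer_forward(v, np.array([[1.0]]), params, slope=0.01)
        expected = np.concatenate([v, np.where(v > 0, v, 0.01 * v)], axis=-1)
        assert np.allclose(out, expected, atol=1e-12)

    def test_hand_computed_three_nodes(self, rng):
        V = rng.normal(size=(3, 2))
        A = rng.uniform(0.1, 1.0, size=(3, 3))
        A /= A.sum(axis=1, keepdims=True)
        W = rng.normal(size=(2, 4))
        b = rng.normal(size=(4,))
        out = layer_forward(V, A, {"W": W, "b": b}, slope=0.01)
        pre = A @ V @ W + b
        expected = np.concatenate([V, np.where(pre > 0, pre, 0.01 * pre)], axis=-1)
        assert np.abs(out - expected).max() < 1e-10

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            layer_forward(rng.normal(size=(3, 2)), np.ones((4, 4)) / 4, {"W": np.eye(2), "b": np.zeros(2)})


def _episode_from(pipeline, rng_seed=0, k_shot=5, n_query=2):
    return sample_episode(
        pipeline["X_train"], pipeline["y_train"], pipeline["combo"],
        n_way=4, k_shot=k_shot, n_query=n_query, rng=rng_seed,
    )


def _init(pipeline, **overrides):
    model = AutoMetricGNN(
        pipeline["X_train"], pipeline["y_train"], pipeline["combo"],
        k_shot=5, iterations=5, batch_size=4, **overrides,
    )
    params = model.init_params(np.random.default_rng(0))
    return model, params


class TestForward:
    def test_probability_rows_sum_to_one(self, small_pipeline):
        model, params = _init(small_pipeline)
        ep = _episode_from(small_pipeline)
        probs = forward(ep, params, model.config)
        assert probs.shape == (2, 4)
        assert np.abs(probs.sum(axis=-1) - 1.0).max() < 1e-10

    def test_support_permutation_invariance(self, small_pipeline):
        model, params = _init(small_pipeline)
        ep = _episode_from(small_pipeline, rng_seed=5, n_query=1)
        perm = np.random.default_rng(2).permutation(ep.n_support)
        permuted = Episode(
            support_ids=[ep.support_ids[i] for i in perm],
            query_ids=ep.query_ids,
            node_features=np.vstack([ep.node_features[perm], ep.node_features[-1:]]),
            risk_values=np.vstack([ep.risk_values[perm], ep.risk_values[-1:]]),
            support_labels=ep.support_labels[perm],
            query_labels=ep.query_labels,
        )
        p1 = forward(ep, params, model.config)
        p2 = forward(permuted, params, model.config)
        assert np.abs(p1 - p2).max() < 1e-6

    def test_constraints_disabled_equals_identical_risk_rows(self, small_pipeline):
        # E is exactly all-ones when every node shares its risk values
        model_on, params = _init(small_pipeline)
        model_off, _ = _init(small_pipeline, use_constraints=False)
        ep = _episode_from(small_pipeline, rng_seed=9, n_query=1)
        flat = Episode(
            support_ids=ep.support_ids,
            query_ids=ep.query_ids,
            node_features=ep.node_features,
            risk_values=np.zeros_like(ep.risk_values),
            support_labels=ep.support_labels,
            query_labels=ep.query_labels,
        )
        p_flat = forward(flat, params, model_on.config)
        p_off = forward(ep, params, model_off.config)
        assert np.allclose(p_flat, p_off, atol=1e-12)


class TestMetaTraining:
    def test_zero_iterations_leaves_params_at_init(self, small_pipeline):
        model, _ = _init(small_pipeline)
        res = model.fit(iterations=0)
        fresh = model.init_params(np.random.default_rng(model.config.seed))
        for k in fresh:
            assert np.array_equal(res.params[k].data, fresh[k].data)
        assert res.loss_history.size == 0

    def test_loss_history_deterministic(self, small_pipeline):
        model, _ = _init(small_pipeline)
        h1 = model.fit(iterations=4).loss_history
        h2 = model.fit(iterations=4).loss_history
        assert np.array_equal(h1, h2)

    def test_loss_decreases_on_separable_pool(self):
        spec = CohortSpec(n_per_class=(20, 20, 20, 20), p_total=10, p_informative=6,
                          effect_size=3.0, rho=0.0, seed=3)
        table, labels, truth = generate_cohort(spec)
        std, _ = standardize(table)
        combo = build_combination(truth[:2], truth)
        model = AutoMetricGNN(std, labels, combo, k_shot=5, batch_size=8, seed=42)
        res = model.fit(iterations=60)
        assert res.loss_history.size == 60
        assert res.loss_history[-15:].mean() < res.loss_history[:15].mean()

    def test_constraints_require_risk_factors(self, small_pipeline):
        combo = build_combination([], small_pipeline["combo"].node_features)
        with pytest.raises(EpisodeError):
            AutoMetricGNN(
                small_pipeline["X_train"], small_pipeline["y_train"], combo, k_shot=5
            )


@pytest.fixture(scope="module")
def trained_separable():
    spec = CohortSpec(n_per_class=(25, 25, 25, 25), p_total=12, p_informative=8,
                      effect_size=4.0, rho=0.0, seed=19)
    table, labels, truth = generate_cohort(spec)
    std, _ = standardize(table)
    combo = build_combination(truth[:3], truth)
    model = AutoMetricGNN(std, labels, combo, k_shot=5, batch_size=8, seed=42,
                          ensemble_size=3)
    res = model.fit(iterations=120)
    return std, labels, truth, res


class TestPrediction:
    def test_single_episode_prediction_deterministic(self, trained_separable):
        std, labels, truth, res = trained_separable
        sub = std.select_samples(std.sample_ids[:5])
        p1 = res.predict_proba(sub, ensemble=1, seed=11)
        p2 = res.predict_proba(sub, ensemble=1, seed=11)
        assert np.array_equal(p1, p2)

    def test_training_rows_recover_their_own_stage(self, trained_separable):
        # a support sample duplicated as the unknown node keeps its label
        std, labels, truth, res = trained_separable
        ids = std.sample_ids[::5]
        preds, _ = res.predict(std.select_samples(ids), seed=2)
        stages = labels.select_samples(ids).stage
        assert (preds == stages).mean() >= 0.95

    def test_agrees_with_centroid_classifier_in_separable_limit(self, trained_separable):
        std, labels, truth, res = trained_separable
        spec2 = CohortSpec(n_per_class=(10, 10, 10, 10), p_total=12, p_informative=8,
                           effect_size=4.0, rho=0.0, seed=77)
        fresh, fresh_labels, _ = generate_cohort(spec2)
        fresh_std = type(std)(fresh.sample_ids, fresh.feature_names, fresh.values)
        preds, _ = res.predict(fresh_std.select_features(std.feature_names), seed=4)
        node = std.select_features(truth).values
        centroids = np.stack([node[labels.stage == c].mean(axis=0) for c in range(4)])
        fresh_node = fresh_std.select_features(truth).values
        centroid_pred = np.linalg.norm(
            fresh_node[:, None, :] - centroids[None], axis=-1
        ).argmin(axis=1)
        assert (preds == centroid_pred).mean() >= 0.9

    def test_save_load_round_trip(self, trained_separable, tmp_path):
        std, labels, truth, res = trained_separable
        path = tmp_path / "ckpt.json"
        res.save(path)
        back = AMGNNResults.load(path, res.model.table, res.model.labels)
        sub = std.select_samples(std.sample_ids[:4])
        assert np.array_equal(
            res.predict_proba(sub, ensemble=1, seed=0),
            back.predict_proba(sub, ensemble=1, seed=0),
        )

    def test_summary_mentions_episode_shape(self, trained_separable):
        *_, res = trained_separable
        text = res.summary()
        assert "4-way-5-shot" in text and "risk factors" in text
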