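"""Slide-level MIL models: pooling oracle, invariances, gradients."""

import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

import histomil as hm
from histomil import _nn
from histomil.exceptions import DegenerateDataError, ShapeMismatchError
from histomil.slide_models import (_mil_backward, _mil_forward, _mil_init,
                                   _weldon_forward, _weldon_grad_weights,
                                   _weldon_init, weldon_pool)


def sort_pool_oracle(scores, R):
    """Independent full-sort implementation of top/bottom-R averaging."""
    s = sorted(scores)
    r = min(R, len(s))
    return (sum(s[:r]) + sum(s[-r:])) / (2 * r)


class TestWeldonPool:
    def test_worked_case_1_to_300(self):
        assert weldon_pool(np.arange(1, 301), R=100) == 150.5
        assert sort_pool_oracle(range(1, 301), 100) == 150.5

    def test_constant_scores(self):
        for r in (1, 5, 100):
            assert weldon_pool(np.full(37, 2.5), R=r) == 2.5

    def test_single_score_degenerate_clamp(self):
        assert weldon_pool(np.array([3.2]), R=100) == 3.2

    def test_matches_oracle_on_random_cases(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(1, 501))
            r = int(rng.choice([1, 5, 100]))
            s = rng.normal(size=n)
            assert weldon_pool(s, r) == pytest.approx(
                sort_pool_oracle(s, r), abs=1e-12)

    def test_componentwise_on_matrix(self):
        rng = np.random.default_rng(1)
        S = rng.normal(size=(40, 4))
        got = weldon_pool(S, R=7)
        want = [sort_pool_oracle(S[:, c], 7) for c in range(4)]
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            weldon_pool(np.array([]), R=5)

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=80),
           st.integers(1, 120))
    def test_pool_between_min_and_max(self, scores, R):
        v = weldon_pool(np.array(scores), R)
        assert min(scores) - 1e-9 <= v <= max(scores) + 1e-9

    def test_gradient_weights_sum_to_one(self):
        s = np.random.default_rng(2).normal(size=23)
        for r in (1, 5, 100):
            w = _weldon_grad_weights(s, r)
            assert w.sum() == pytest.approx(1.0)


class TestSubsample:
    def test_small_bag_returned_unchanged(self):
        X = np.ones((500, 3))
        assert hm.subsample_tiles(X, 8000, 0) is X

    def test_large_bag_cut_to_max_distinct(self):
        X = np.arange(10_000)[:, None].astype(float)
        sub = hm.subsample_tiles(X, 8000, 0)
        assert sub.shape == (8000, 1)
        assert len(np.unique(sub)) == 8000

    def test_seeded_identical(self):
        X = np.random.default_rng(0).normal(size=(100, 2))
        a = hm.subsample_tiles(X, 10, 5)
        b = hm.subsample_tiles(X, 10, 5)
        np.testing.assert_array_equal(a, b)


@pytest.fixture(scope="module")
def mil_fit(gated_small):
    gated, y = gated_small
    res = hm.AttentionMILClassifier(gated, y).fit(
        hm.TrainConfig(seed=0, max_epochs=4))
    return gated, y, res


@pytest.fixture(scope="module")
def weldon_fit(gated_small, small_cohort):
    gated, _ = gated_small
    comp = {p.patient_id: p.components.as_array()
            for p in small_cohort.patients}
    Y = np.vstack([comp[b.patient_id] for b in gated])
    res = hm.WeldonRegressor(gated, Y, R=100).fit(
        hm.TrainConfig(seed=0, max_epochs=4))
    return gated, Y, res


class TestAttentionMIL:
    def test_single_tile_attention_is_one(self, mil_fit):
        gated, _, res = mil_fit
        score, w = res.predict(gated[0].features[:1])
        assert w.shape == (1,) and w[0] == pytest.approx(1.0)
        assert 0 < score < 1

    def test_attention_weights_normalized(self, mil_fit):
        gated, _, res = mil_fit
        for b in gated:
            _, w = res.predict(b)
            assert np.all(w >= 0)
            assert w.sum() == pytest.approx(1.0, abs=1e-6)

    def test_permutation_invariance(self, mil_fit):
        gated, _, res = mil_fit
        X = gated[0].features
        perm = np.random.default_rng(1).permutation(len(X))
        s0, w0 = res.predict(X)
        s1, w1 = res.predict(X[perm])
        assert s1 == pytest.approx(s0, abs=1e-6)
        np.testing.assert_allclose(w1, w0[perm], atol=1e-9)

    def test_duplication_invariance(self, mil_fit):
        gated, _, res = mil_fit
        X = gated[1].features
        s0, _ = res.predict(X)
        s1, _ = res.predict(np.vstack([X, X]))
        assert s1 == pytest.approx(s0, abs=1e-6)

    def test_empty_slide_rejected(self, mil_fit):
        _, _, res = mil_fit
        with pytest.raises(ValueError):
            res.predict(np.zeros((0, res.d)))

    def test_zero_epochs_returns_init(self, gated_small):
        gated, y = gated_small
        res = hm.AttentionMILClassifier(gated, y).fit(
            hm.TrainConfig(seed=9, max_epochs=0))
        init = _mil_init(gated[0].d, np.random.default_rng(9))
        for k in init:
            np.testing.assert_array_equal(res.params[k], init[k])

    def test_single_class_rejected(self, gated_small):
        gated, _ = gated_small
        with pytest.raises(DegenerateDataError):
            hm.AttentionMILClassifier(gated, np.zeros(len(gated))).fit()

    def test_empty_bags_skipped_with_warning(self, gated_small):
        gated, y = gated_small
        bags = [gated[0].features, np.zeros((0, gated[0].d))]
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            model = hm.AttentionMILClassifier(bags, np.array([1.0, 0.0]))
        assert len(model.bags) == 1
        assert any("zero gated tiles" in str(x.message) for x in w)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 5))
        params = _mil_init(5, rng)
        p, _, cache = _mil_forward(params, X)
        grads = _mil_backward(params, cache, p, 1.0)

        def loss(pr):
            q, _, _ = _mil_forward(pr, X)
            return _nn.bce_loss(np.array([q]), np.array([1.0]))

        fd = _nn.finite_difference_grads(loss, params, h=1e-6)
        for k in params:
            np.testing.assert_allclose(grads[k], fd[k], atol=5e-5,
                                       err_msg=k)

    def test_save_load_roundtrip(self, mil_fit, tmp_path):
        gated, _, res = mil_fit
        res.save(tmp_path / "bc.npz")
        loaded = hm.AttentionMILResults.load(tmp_path / "bc.npz")
        s0, _ = res.predict(gated[0])
        s1, _ = loaded.predict(gated[0])
        assert s0 == pytest.approx(s1)


class TestWeldonModel:
    def test_tile_scores_match_hand_forward(self, weldon_fit):
        gated, _, res = weldon_fit
        x3 = gated[0].features[:3]
        H = np.maximum(x3 @ res.params["l1_W"] + res.params["l1_b"], 0)
        want = H @ res.params["l2_W"] + res.params["l2_b"]
        np.testing.assert_allclose(res.score_tiles(x3), want, atol=1e-12)

    def test_slide_prediction_is_pooled_tile_scores(self, weldon_fit):
        gated, _, res = weldon_fit
        X = gated[2].features
        S = res.score_tiles(X)
        want = [sort_pool_oracle(S[:, c], res.R) for c in range(4)]
        np.testing.assert_allclose(res.predict(X), want, atol=1e-12)

    def test_single_tile_slide_predicts_its_scores(self, weldon_fit):
        gated, _, res = weldon_fit
        x1 = gated[0].features[:1]
        np.testing.assert_allclose(res.predict(x1),
                                   res.score_tiles(x1)[0], atol=1e-12)

    def test_duplicate_tile_duplicate_row(self, weldon_fit):
        gated, _, res = weldon_fit
        X = np.vstack([gated[0].features[0]] * 2)
        S = res.score_tiles(X)
        np.testing.assert_array_equal(S[0], S[1])

    def test_permutation_invariance_of_slide_output(self, weldon_fit):
        gated, _, res = weldon_fit
        X = gated[0].features
        perm = np.random.default_rng(2).permutation(len(X))
        np.testing.assert_allclose(res.predict(X[perm]), res.predict(X),
                                   atol=1e-6)

    def test_identical_tiles_slide_equals_tile(self, weldon_fit):
        gated, _, res = weldon_fit
        X = np.tile(gated[0].features[0], (30, 1))
        np.testing.assert_allclose(res.predict(X), res.score_tiles(X)[0],
                                   atol=1e-12)

    def test_zero_epochs_returns_init(self, gated_small):
        gated, _ = gated_small
        Y = np.zeros((len(gated), 4))
        res = hm.WeldonRegressor(gated, Y).fit(hm.TrainConfig(seed=5,
                                                              max_epochs=0))
        init = _weldon_init(gated[0].d, np.random.default_rng(5))
        for k in init:
            np.testing.assert_array_equal(res.params[k], init[k])

    def test_constant_labels_drive_loss_to_zero(self):
        rng = np.random.default_rng(6)
        bags = [rng.normal(size=(20, 4)) for _ in range(12)]
        Y = np.tile([0.3, -0.2, 0.1, 0.5], (12, 1))
        res = hm.WeldonRegressor(bags, Y, R=5).fit(
            hm.TrainConfig(seed=0, max_epochs=60, val_fraction=0.0,
                           patience=60))
        assert res.train_loss[-1] < 0.05 * res.train_loss[0]

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(9, 4))
        y = rng.normal(size=4)
        params = _weldon_init(4, rng)

        def loss(pr):
            S, _ = _weldon_forward(pr, X)
            return float(np.sum((weldon_pool(S, 3) - y) ** 2))

        S, H = _weldon_forward(params, X)
        resid = weldon_pool(S, 3) - y
        dS = np.empty_like(S)
        for c in range(4):
            dS[:, c] = 2 * resid[c] * _weldon_grad_weights(S[:, c], 3)
        grads = {"l2_W": H.T @ dS, "l2_b": dS.sum(axis=0)}
        dH = dS @ params["l2_W"].T
        dH[H <= 0] = 0
        grads["l1_W"] = X.T @ dH
        grads["l1_b"] = dH.sum(axis=0)
        fd = _nn.finite_difference_grads(loss, params, h=1e-6)
        for k in params:
            np.testing.assert_allclose(grads[k], fd[k], atol=5e-5, err_msg=k)

    def test_labels_shape_checked(self, gated_small):
        gated, _ = gated_small
        with pytest.raises(ShapeMismatchError):
            hm.WeldonRegressor(gated, np.zeros((len(gated), 3)))

    def test_save_load_roundtrip(self, weldon_fit, tmp_path):
        gated, _, res = weldon_fit
        res.save(tmp_path / "w.npz")
        loaded = hm.WeldonResults.load(tmp_path / "w.npz")
        np.testing.assert_allclose(loaded.predict(gated[0]),
                                   res.predict(gated[0]))
        assert loaded.R == res.R


class TestPatientAggregation:
    def test_mean_rule(self):
        agg = hm.patient_scores(np.array([0.2, 0.4, 1.0]),
                                ["a", "a", "b"])
        assert agg["a"] == pytest.approx(0.3)
        assert agg["b"] == pytest.approx(1.0)

    def test_max_rule(self):
        agg = hm.patient_scores(np.array([0.2, 0.4, 1.0]),
                                ["a", "a", "b"], rule="max")
        assert agg["a"] == pytest.approx(0.4)
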