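import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protlabel.alphabets import PAD_INDEX, SYMBOLS
from protlabel.exceptions import ConfigError
from protlabel.network import (
    EmbeddingTable,
    Hyperparams,
    NetworkParams,
    WindowExample,
    assemble_features,
    backward,
    forward,
    forward_batch,
    gradient_check,
    init_params,
    load_checkpoint,
    nll_loss,
    save_checkpoint,
    sgd_step,
    softmax,
    transfer,
)


def _random_example(params, rng, K):
    tok = rng.integers(0, len(SYMBOLS), size=params.window)
    prof = rng.random((params.window, 20)) if params.use_profile else None
    return WindowExample(tok, prof, label=int(rng.integers(K)))


class TestInit:
    def test_same_seed_bitwise_identical(self):
        a = init_params(5, {"t": 3}, 8, 4, True, seed=11)
        b = init_params(5, {"t": 3}, 8, 4, True, seed=11)
        assert np.array_equal(a.embedding.weights, b.embedding.weights)
        assert np.array_equal(a.hidden[0].W, b.hidden[0].W)
        assert np.array_equal(a.task_outputs["t"].W, b.task_outputs["t"].W)

    def test_centered_distribution(self):
        params = init_params(9, {"t": 3}, 200, 10, True, seed=0)
        W = params.hidden[0].W
        r = 1.0 / np.sqrt(W.shape[1])
        se = (2 * r) / np.sqrt(12 * W.size)  # SE of the mean of U[-r, r]
        assert abs(W.mean()) < 3 * se
        assert np.abs(W).max() <= r

    def test_embedding_shape_covers_dictionary(self):
        params = init_params(5, {"t": 2}, 4, 15, True, seed=0)
        assert params.embedding.weights.shape == (15, len(SYMBOLS))

    def test_invalid_architectures_rejected(self):
        with pytest.raises(ConfigError):
            init_params(4, {"t": 2}, 8, 4, True, seed=0)  # even window
        with pytest.raises(ConfigError):
            init_params(5, {"t": 2}, 0, 4, True, seed=0)  # empty layer
        with pytest.raises(ConfigError):
            init_params(5, {}, 8, 4, True, seed=0)        # no tasks
        with pytest.raises(ConfigError):
            init_params(5, {"t": 2}, 8, None, False, seed=0)  # no features


class TestFeatures:
    def test_embedding_only_layout(self, rng):
        emb = EmbeddingTable.random(2, rng)
        tok = np.array([0, 5, 9])
        x = assemble_features(WindowExample(tok), emb, use_profile=False)
        expected = np.concatenate([emb.weights[:, t] for t in tok])
        assert x.shape == (6,)
        assert np.array_equal(x, expected)

    def test_profile_and_embedding_length(self, rng):
        emb = EmbeddingTable.random(2, rng)
        ex = WindowExample(np.array([0, 1, 2]), rng.random((3, 20)))
        assert assemble_features(ex, emb, True).shape == (3 * 22,)

    def test_padding_position_uses_pad_column_and_zero_profile(self, rng):
        emb = EmbeddingTable.random(3, rng)
        prof = np.vstack([np.zeros(20), rng.random(20), rng.random(20)])
        ex = WindowExample(np.array([PAD_INDEX, 4, 5]), prof)
        x = assemble_features(ex, emb, True)
        assert np.array_equal(x[:3], emb.weights[:, PAD_INDEX])
        assert np.all(x[3:23] == 0)


class TestTransferAndSoftmax:
    @pytest.mark.parametrize("x, y", [(0.5, 0.5), (-3.0, -1.0), (1.0, 1.0), (7.2, 1.0)])
    def test_hard_tanh(self, x, y):
        assert transfer(np.array([x])).item() == y

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_posterior_rows_normalize(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 8))
        params = init_params(3, {"t": K}, int(rng.integers(2, 10)),
                             int(rng.integers(2, 6)), False, rng)
        X = rng.normal(scale=3.0, size=(5, params.feature_dim))
        probs = forward_batch(X, params, "t")
        assert np.all(probs > 0) and np.all(probs < 1)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_weights_give_uniform(self):
        params = init_params(3, {"t": 4}, 5, 2, False, seed=0)
        for layer in params.hidden + [params.task_outputs["t"]]:
            layer.W[:] = 0
            layer.b[:] = 0
        probs = forward(np.zeros(params.feature_dim), params, "t")
        assert np.allclose(probs, 0.25)

    def test_hand_computed_softmax(self):
        # identity-sized net: 2 features -> 2 hidden (weights chosen inside
        # the linear region) -> 3 classes with hand-set output weights
        params = init_params(1, {"t": 3}, 2, 2, False, seed=0)
        params.hidden[0].W[:] = np.eye(2) * 0.5
        params.hidden[0].b[:] = 0
        params.task_outputs["t"].W[:] = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        params.task_outputs["t"].b[:] = np.array([0.0, 0.1, -0.2])
        x = np.array([0.4, -0.6])
        z = np.array([0.2, -0.3 + 0.1, 0.2 - 0.3 - 0.2])
        expected = np.exp(z) / np.exp(z).sum()
        assert np.allclose(forward(x, params, "t"), expected, atol=1e-12)

    def test_unregistered_task_is_lookup_error(self):
        params = init_params(3, {"t": 2}, 4, 2, False, seed=0)
        with pytest.raises(LookupError):
            forward(np.zeros(params.feature_dim), params, "nope")


class TestLoss:
    @pytest.mark.parametrize(
        "posterior, label, expected",
        [
            (np.array([1.0, 0.0]), 0, 0.0),
            (np.array([0.5, 0.5]), 1, np.log(2)),
            (np.full(4, 0.25), 2, np.log(4)),
        ],
    )
    def test_closed_forms(self, posterior, label, expected):
        assert nll_loss(posterior, label) == pytest.approx(expected)

    def test_zero_posterior_clipped(self):
        loss = nll_loss(np.array([1.0, 0.0]), 1)
        assert loss == pytest.approx(-np.log(1e-12))


class TestBackward:
    def test_matches_finite_differences(self, rng):
        worst = 0.0
        for _ in range(15):
            w = int(rng.choice([3, 5]))
            K = int(rng.integers(2, 5))
            use_prof = bool(rng.integers(2))
            d = None if (use_prof and rng.integers(2)) else int(rng.integers(2, 5))
            params = init_params(w, {"t": K}, int(rng.integers(3, 8)), d,
                                 use_prof, rng)
            ex = _random_example(params, rng, K)
            worst = max(worst, gradient_check(params, ex, "t"))
        assert worst <= 1e-4

    def test_softmax_nll_output_gradient_is_posterior_minus_onehot(self, rng):
        params = init_params(3, {"t": 3}, 4, 2, False, rng)
        ex = _random_example(params, rng, 3)
        feats = assemble_features(ex, params.embedding, False)
        probs = forward(feats, params, "t")
        grads = backward(ex, params, "t", ex.label)
        onehot = np.zeros(3)
        onehot[ex.label] = 1
        assert np.allclose(grads.task_outputs["t"].b, probs - onehot, atol=1e-12)

    def test_absent_tokens_have_zero_embedding_gradient(self, rng):
        params = init_params(3, {"t": 2}, 4, 3, False, rng)
        ex = WindowExample(np.array([1, 2, 3]), label=0)
        grads = backward(ex, params, "t", 0)
        untouched = [j for j in range(len(SYMBOLS)) if j not in (1, 2, 3)]
        assert np.all(grads.embedding[:, untouched] == 0)


class TestSgdStep:
    def test_lr_zero_leaves_params_unchanged(self, rng):
        params = init_params(3, {"t": 2}, 4, 2, True, rng)
        snapshot = copy.deepcopy(params)
        sgd_step(params, _random_example(params, rng, 2), "t", lr=0.0)
        assert np.array_equal(params.hidden[0].W, snapshot.hidden[0].W)
        assert np.array_equal(params.embedding.weights, snapshot.embedding.weights)

    def test_small_step_decreases_loss(self, rng):
        params = init_params(3, {"t": 3}, 5, 2, False, rng)
        ex = _random_example(params, rng, 3)
        feats = assemble_features(ex, params.embedding, False)
        before = nll_loss(forward(feats, params, "t"), ex.label)
        sgd_step(params, ex, "t", lr=0.01)
        feats = assemble_features(ex, params.embedding, False)
        after = nll_loss(forward(feats, params, "t"), ex.label)
        assert after < before


class TestCheckpoint:
    def test_save_load_forward_identical(self, tmp_path, rng):
        params = init_params(5, {"a": 3, "b": 2}, 7, 4, True, rng)
        path = tmp_path / "model.npz"
        save_checkpoint(params, path, {"note": "unit"})
        loaded, meta = load_checkpoint(path)
        assert meta == {"note": "unit"}
        ex = _random_example(params, rng, 3)
        feats = assemble_features(ex, params.embedding, True)
        feats2 = assemble_features(ex, loaded.embedding, True)
        assert np.array_equal(
            forward(feats, params, "a"), forward(feats2, loaded, "a")
        )
        assert np.array_equal(
            forward(feats, params, "b"), forward(feats2, loaded, "b")
        )
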