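"""Feature extractor: shapes, attention algebra, loss identities, gradients,
training semantics."""

import math

import numpy as np
import pytest

import fitrx as fx
from fitrx.extractor import (
    Extractor,
    ExtractorConfig,
    batch_loss_and_grads,
    load_checkpoint,
    mask_channels,
    save_checkpoint,
)
from fitrx.preprocess import tensorize


def _rand_tensor(n, rng=None):
    rng = rng or np.random.default_rng(0)
    return rng.normal(size=(n, 15, 4))


class TestConvBlock:
    def test_length_chain_default(self):
        assert fx.conv_output_lengths(15, 3, 2) == [8, 4, 2]

    def test_default_shapes_end_to_end(self):
        model = Extractor(ExtractorConfig())
        h = model.conv_forward(_rand_tensor(3))
        assert h.shape == (3, 2, 256)
        h_attn, a = model.attention_forward(h)
        assert h_attn.shape == (3, 2, 256)
        assert a.shape == (3, 8, 2, 2)
        z = model.pool(h_attn)
        assert z.shape == (3, 256)
        assert model.config.head_dim == 32

    def test_relu_nonnegative_and_zero_input(self, tiny_cfg):
        model = Extractor(tiny_cfg)
        assert (model.conv_forward(_rand_tensor(4)) >= 0).all()
        # zero input, zero bias (init) -> identically zero output
        assert not model.conv_forward(np.zeros((2, 15, 4))).any()

    def test_matches_direct_convolution_oracle(self, tiny_cfg):
        """First conv layer against a brute-force strided correlation with
        explicit ceil 'same' zero padding."""
        model = Extractor(tiny_cfg)
        x = _rand_tensor(2)
        w, b = model.params["W0"], model.params["b0"]
        k, stride = tiny_cfg.kernel, tiny_cfg.stride
        l_out = math.ceil(15 / stride)
        pad_total = max((l_out - 1) * stride + k - 15, 0)
        pl = pad_total // 2
        xp = np.zeros((2, 15 + pad_total, 4))
        xp[:, pl : pl + 15, :] = x
        expected = np.zeros((2, l_out, w.shape[2]))
        for n in range(2):
            for t in range(l_out):
                for o in range(w.shape[2]):
                    acc = b[o]
                    for dk in range(k):
                        for c in range(4):
                            acc += xp[n, t * stride + dk, c] * w[dk, c, o]
                    expected[n, t, o] = max(acc, 0.0)
        got = model._conv_layer(x, 0)[0]
        assert np.allclose(got, expected, atol=1e-12)


class TestAttention:
    def test_rows_stochastic(self, tiny_cfg):
        model = Extractor(tiny_cfg)
        _, a = model.attention_forward(model.conv_forward(_rand_tensor(5)))
        assert np.abs(a.sum(axis=-1) - 1).max() < 1e-6
        assert (a >= 0).all()

    def test_zero_query_key_gives_uniform_attention(self, tiny_cfg):
        model = Extractor(tiny_cfg)
        model.params["Wq"][:] = 0
        model.params["Wk"][:] = 0
        h = model.conv_forward(_rand_tensor(3))
        _, a = model.attention_forward(h)
        t = h.shape[1]
        assert np.allclose(a, 1.0 / t)

    def test_single_position_identity(self, tiny_cfg):
        model = Extractor(tiny_cfg)
        d = tiny_cfg.d
        h = np.random.default_rng(1).normal(size=(2, 1, d))
        h_attn, a = model.attention_forward(h)
        assert np.allclose(a, 1.0)
        # output = LayerNorm(H + V Wo) with attention weight exactly 1
        nh, dh = tiny_cfg.heads, tiny_cfg.head_dim
        v = (h @ model.params["Wv"]).reshape(2, 1, nh, dh).transpose(0, 2, 1, 3)
        concat = v.transpose(0, 2, 1, 3).reshape(2, 1, d)
        r = h + concat @ model.params["Wo"]
        xhat = (r - r.mean(-1, keepdims=True)) / np.sqrt(r.var(-1, keepdims=True) + 1e-5)
        assert np.allclose(h_attn, model.params["gamma"] * xhat + model.params["beta"])

    def test_width_mismatch_rejected(self, tiny_cfg):
        model = Extractor(tiny_cfg)
        with pytest.raises(ValueError, match="width"):
            model.attention_forward(np.zeros((2, 2, tiny_cfg.d + 1)))


class TestPool:
    def test_constant_in_time(self, tiny_cfg):
        model = Extractor(tiny_cfg)
        c = np.random.default_rng(2).normal(size=(3, 1, 8))
        h = np.repeat(c, 4, axis=1)
        assert np.allclose(model.pool(h), c[:, 0, :])

    def test_two_step_mean(self, tiny_cfg):
        model = Extractor(tiny_cfg)
        h = np.stack([np.full((2, 8), 1.0), np.full((2, 8), 3.0)], axis=1)
        assert np.allclose(model.pool(h), 2.0)

    def test_matches_mean_oracle(self, tiny_cfg):
        model = Extractor(tiny_cfg)
        h = np.random.default_rng(3).normal(size=(4, 6, 8))
        assert np.allclose(model.pool(h), h.sum(axis=1) / 6, atol=1e-6)

    def test_empty_time_axis_rejected(self, tiny_cfg):
        with pytest.raises(ValueError):
            Extractor(tiny_cfg).pool(np.zeros((2, 0, 8)))


class TestSparsityPenalty:
    def test_one_hot_rows_zero(self):
        a = np.zeros((2, 2, 3, 3))
        a[..., 0] = 1.0
        assert fx.attention_sparsity_penalty(a) == 0.0

    def test_uniform_two_positions(self):
        a = np.full((1, 1, 2, 2), 0.5)
        assert fx.attention_sparsity_penalty(a) == pytest.approx(math.log(2))

    def test_mixed_map_mean_of_row_entropies(self):
        rows = np.array([[0.5, 0.5], [1.0, 0.0], [0.25, 0.75]])
        a = rows.reshape(1, 1, 3, 2)
        by_hand = np.mean([
            -(0.5 * math.log(0.5)) * 2,
            0.0,
            -(0.25 * math.log(0.25) + 0.75 * math.log(0.75)),
        ])
        assert fx.attention_sparsity_penalty(a) == pytest.approx(by_hand)

    def test_unnormalized_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            fx.attention_sparsity_penalty(np.full((1, 1, 2, 2), 0.6))


ONE_HOT = np.array([[[[1.0, 0.0], [0.0, 1.0]]]])


class TestTotalLoss:
    def test_equal_components_weights_normalize(self):
        assert fx.total_loss([0.7] * 4, ONE_HOT) == pytest.approx(0.7)

    def test_single_component(self):
        assert fx.total_loss([1, 0, 0, 0], ONE_HOT) == pytest.approx(0.4)

    def test_uniform_attention_penalty(self):
        uniform = np.full((1, 1, 2, 2), 0.5)
        assert fx.total_loss([0.0] * 4, uniform) == pytest.approx(0.1 * math.log(2))

    def test_nan_component_is_failure(self):
        with pytest.raises(FloatingPointError):
            fx.total_loss([math.nan, 0, 0, 0], ONE_HOT)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        cfg = ExtractorConfig(conv_filters=(6, 8, 8), heads=2, attn_dropout=0.0,
                              hidden_noise=0.0, l2=1e-4, seed=7)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 15, 4))
        y = np.array([0, 1, 2, 3])
        model = Extractor(cfg)
        _, grads = batch_loss_and_grads(model, x, y, train=False)
        eps = 1e-6
        for name, w in model.params.items():
            flat_idx = rng.choice(w.size, size=min(3, w.size), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, w.shape)
                orig = w[idx]
                w[idx] = orig + eps
                lp, _ = batch_loss_and_grads(model, x, y, train=False)
                w[idx] = orig - eps
                lm, _ = batch_loss_and_grads(model, x, y, train=False)
                w[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[name][idx]
                assert abs(num - ana) <= 1e-4 * max(1.0, abs(num)), name

    def test_penalty_ablation_nonnegative(self, tiny_cfg):
        """Removing the attention regularizer can only lower the loss."""
        x = _rand_tensor(6)
        y = np.array([0, 1, 2, 3, 0, 1])
        with_pen = Extractor(tiny_cfg)
        loss_with, _ = batch_loss_and_grads(with_pen, x, y, train=False)
        cfg0 = ExtractorConfig(**{**tiny_cfg.__dict__, "lambda_attn": 0.0})
        without = Extractor(cfg0, rng=np.random.default_rng(tiny_cfg.seed))
        loss_without, _ = batch_loss_and_grads(without, x, y, train=False)
        assert loss_with >= loss_without


class TestMasking:
    def test_mask_keeps_one_channel(self):
        x = _rand_tensor(2)
        for m in range(4):
            xm = mask_channels(x, m)
            assert np.array_equal(xm[:, :, m], x[:, :, m])
            others = [c for c in range(4) if c != m]
            assert not xm[:, :, others].any()


class TestTraining:
    def test_eval_mode_determinism(self, trained_tiny):
        model, _, fold = trained_tiny
        t = tensorize(fold.X_val[:10])
        z1, z2 = model.embed(t), model.embed(t)
        assert np.array_equal(z1, z2)

    def test_same_seed_bitwise_identical_runs(self, cohort_600, tiny_cfg):
        _, X, y = cohort_600
        Xs, _ = fx.standardize(X[:120])
        t = tensorize(Xs)
        runs = []
        for _ in range(2):
            model, _ = fx.train_extractor(t[:100], y[:100], t[100:], y[100:120], tiny_cfg)
            runs.append(model.params)
        for k in runs[0]:
            assert np.array_equal(runs[0][k], runs[1][k])

    def test_early_stopping_counter_semantics(self, cohort_600, tiny_cfg):
        """With lr = 0 the validation loss never improves after epoch 1, so
        training stops exactly at epoch 1 + patience."""
        _, X, y = cohort_600
        Xs, _ = fx.standardize(X[:80])
        t = tensorize(Xs)
        cfg = ExtractorConfig(**{**tiny_cfg.__dict__, "lr": 0.0, "patience": 4,
                                 "max_epochs": 50})
        _, hist = fx.train_extractor(t[:60], y[:60], t[60:], y[60:80], cfg)
        assert hist["best_epoch"] == 1
        assert hist["stopped_epoch"] == 5

    def test_training_loss_halves_on_separable_toy(self):
        """Two categories with distinct fatigue slopes and metric levels:
        the loss should fall by >= 50% within 30 epochs."""
        recs = fx.generate_cohort(
            fx.CohortSpec(n=200, class_proportions=(0.0, 0.5, 0.0, 0.5), seed=13)
        )
        X, y = fx.records_to_compact(recs)
        Xs, _ = fx.standardize(X)
        t = tensorize(Xs)
        cfg = ExtractorConfig(conv_filters=(8, 16, 16), heads=4, max_epochs=30,
                              patience=30, batch_size=64, attn_dropout=0.0,
                              hidden_noise=0.0, seed=3)
        _, hist = fx.train_extractor(t[:160], y[:160], t[160:], y[160:], cfg)
        assert hist["train_loss"][-1] <= 0.5 * hist["train_loss"][0]

    def test_empty_training_set_rejected(self, tiny_cfg):
        with pytest.raises(ValueError):
            fx.train_extractor(np.zeros((0, 15, 4)), np.zeros(0, int),
                               np.zeros((1, 15, 4)), np.zeros(1, int), tiny_cfg)


class TestConfigValidation:
    def test_width_not_divisible_by_heads(self):
        with pytest.raises(ValueError, match="divisible"):
            ExtractorConfig(conv_filters=(8, 8, 10), heads=4)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ExtractorConfig(metric_weights=(0.5, 0.2, 0.2, 0.2))


class TestCheckpoint:
    def test_round_trip_identical_embeddings(self, trained_tiny, tmp_path):
        model, _, fold = trained_tiny
        path = tmp_path / "model.ckpt"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        t = tensorize(fold.X_val[:5])
        assert np.array_equal(model.embed(t), loaded.embed(t))
        assert loaded.config == model.config
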