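import numpy as np
import pytest

from depspeech import nn
from depspeech.network import (AttentionParams, HighwayParams, ModelConfig,
                               attention_pool, build_1dcbbg, build_3dcbhga,
                               highway_forward, multichannel_conv)
from depspeech.training import predict


class TestHighway:
    def test_hand_evaluated_scalar_case(self):
        # W_H=1, b_H=0, W_T=0, b_T=0, x=-2: H=relu(-2)=0, T=0.5 -> output -1
        params = HighwayParams([[1.0]], [0.0], [[0.0]], [0.0])
        out = highway_forward(np.array([[-2.0]]), params)
        np.testing.assert_allclose(out, [[-1.0]])

    def test_saturated_gate_passes_transform(self):
        rng = np.random.default_rng(0)
        W = rng.normal(size=(4, 4))
        params = HighwayParams(W, np.zeros(4), np.zeros((4, 4)), np.full(4, 50.0))
        x = rng.normal(size=(3, 4))
        H = np.maximum(x @ W, 0.0)
        np.testing.assert_allclose(highway_forward(x, params), H, atol=1e-9)

    def test_closed_gate_is_identity(self):
        rng = np.random.default_rng(1)
        params = HighwayParams(rng.normal(size=(4, 4)), np.zeros(4),
                               np.zeros((4, 4)), np.full(4, -50.0))
        x = rng.normal(size=(3, 4))
        np.testing.assert_allclose(highway_forward(x, params), x, atol=1e-9)

    def test_width_mismatch(self):
        params = HighwayParams(np.eye(3), np.zeros(3), np.eye(3), np.zeros(3))
        with pytest.raises(ValueError):
            highway_forward(np.zeros((2, 4)), params)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            HighwayParams(np.zeros((3, 4)), np.zeros(4), np.eye(3), np.zeros(3))


class TestAttentionPool:
    def test_zero_scores_give_mean(self):
        P = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        out = attention_pool(P, AttentionParams(np.zeros(2)))
        np.testing.assert_allclose(out, P.mean(axis=0))

    def test_hand_softmax(self):
        P = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = attention_pool(P, AttentionParams([np.log(3.0), 0.0]))
        np.testing.assert_allclose(out, [0.75, 0.25])

    def test_shift_invariance(self):
        # a constant added to every logit leaves the weights unchanged:
        # append a constant column so W.p_t picks up a uniform +c
        rng = np.random.default_rng(2)
        P = rng.normal(size=(5, 3))
        W = rng.normal(size=3)
        base = attention_pool(P, AttentionParams(W))
        for c in (7.0, -300.0, 300.0):
            P_aug = np.hstack([P, np.ones((5, 1))])
            W_aug = np.concatenate([W, [c]])
            shifted = attention_pool(P_aug, AttentionParams(W_aug))
            np.testing.assert_allclose(shifted[:3], base, atol=1e-9)

    def test_output_in_convex_hull(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(6, 4))
        out = attention_pool(P, AttentionParams(rng.normal(size=4)))
        assert np.all(out >= P.min(axis=0) - 1e-12)
        assert np.all(out <= P.max(axis=0) + 1e-12)

    def test_extreme_logits_stay_finite(self):
        P = np.array([[1000.0], [-1000.0]])
        out = attention_pool(P, AttentionParams([1.0]))
        assert np.isfinite(out).all()

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            attention_pool(np.empty((0, 3)), AttentionParams(np.zeros(3)))


class TestMultichannelConv:
    def test_1d_shape_contract(self):
        cfg = ModelConfig(conv_dims="1d", kernel_sizes=(1, 2, 3, 4),
                          filters_per_branch=32)
        rng = np.random.default_rng(4)
        params = [(rng.normal(size=(k, 40, 32)), np.zeros(32))
                  for k in cfg.kernel_sizes]
        out = multichannel_conv(rng.normal(size=(100, 40)), cfg, params)
        assert out.shape == (100, 128)

    def test_identity_kernel_recovers_channel(self):
        cfg = ModelConfig(conv_dims="1d", kernel_sizes=(1,), filters_per_branch=1)
        W = np.zeros((1, 40, 1))
        W[0, 0, 0] = 1.0
        x = np.random.default_rng(5).normal(size=(30, 40))
        out = multichannel_conv(x, cfg, [(W, np.zeros(1))])
        np.testing.assert_allclose(out[:, 0], x[:, 0], atol=1e-12)

    def test_2d_preserves_frame_axis(self):
        cfg = ModelConfig(conv_dims="2d", kernel_sizes=(2, 3), filters_per_branch=4)
        rng = np.random.default_rng(6)
        params = [(rng.normal(size=(k, k, 3, 4)), np.zeros(4))
                  for k in cfg.kernel_sizes]
        out = multichannel_conv(rng.normal(size=(50, 40, 3)), cfg, params)
        assert out.shape == (50, 40, 8)


def tiny_3d_config(**kw):
    base = dict(conv_dims="2d", kernel_sizes=(1, 2, 3), filters_per_branch=2,
                gru_units=3, pool_size=2, second_conv_filters=2, dropout=0.0)
    base.update(kw)
    return ModelConfig(**base)


def tiny_1d_config(**kw):
    base = dict(conv_dims="1d", kernel_sizes=(1, 2), filters_per_branch=2,
                gru_units=3, pool_size=2, second_conv_filters=2, dropout=0.0)
    base.update(kw)
    return ModelConfig(**base)


class TestArchitectures:
    def test_1d_softmax_contract(self):
        model = build_1dcbbg(tiny_1d_config(), input_length=12, input_dim=39)
        X = np.random.default_rng(7).normal(size=(2, 12, 39))
        probs, labels = predict(model, X)
        assert probs.shape == (2, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert set(labels) <= {0, 1}

    def test_3d_softmax_contract(self):
        model = build_3dcbhga(tiny_3d_config(), n_mel=8)
        X = np.random.default_rng(8).normal(size=(2, 10, 8, 3))
        probs, _ = predict(model, X)
        assert probs.shape == (2, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_deterministic_forward(self):
        model = build_3dcbhga(tiny_3d_config(), n_mel=8, seed=3)
        X = np.random.default_rng(9).normal(size=(2, 10, 8, 3))
        p1, _ = predict(model, X)
        p2, _ = predict(model, X)
        np.testing.assert_array_equal(p1, p2)

    def test_attention_weights_sum_to_one_per_sample(self):
        model = build_3dcbhga(tiny_3d_config(), n_mel=8)
        X = np.random.default_rng(10).normal(size=(3, 10, 8, 3))
        mask = np.ones((3, 10), dtype=bool)
        mask[1, 6:] = False
        predict(model, X, mask=mask)
        alpha = model.attention.last_alpha
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-6)
        # padded steps get (numerically) zero attention
        assert alpha[1, 3:].max() < 1e-6

    def test_masked_steps_have_zero_weight_after_pooling(self):
        model = build_3dcbhga(tiny_3d_config(), n_mel=8)
        X = np.random.default_rng(11).normal(size=(1, 12, 8, 3))
        mask = np.ones((1, 12), dtype=bool)
        mask[0, 8:] = False  # pooled steps 4 and 5 are fully padded
        predict(model, X, mask=mask)
        assert model.attention.last_alpha[0, 4:].max() < 1e-6

    def test_no_highway_ablation_builds_and_runs(self):
        model = build_3dcbhga(tiny_3d_config(n_highway=0), n_mel=8)
        probs, _ = predict(model, np.zeros((1, 10, 8, 3)))
        assert probs.shape == (1, 2)

    def test_batch_permutation_equivariance(self):
        model = build_3dcbhga(tiny_3d_config(), n_mel=8)
        X = np.random.default_rng(12).normal(size=(4, 10, 8, 3))
        probs, _ = predict(model, X)
        perm = [2, 0, 3, 1]
        probs_perm, _ = predict(model, X[perm])
        np.testing.assert_allclose(probs_perm, probs[perm], atol=1e-6)

    def test_parameter_count_grows_with_filters(self):
        def count(f):
            m = build_3dcbhga(tiny_3d_config(filters_per_branch=f), n_mel=8)
            return sum(p.data.size for p in m.parameters())
        assert count(2) < count(4) < count(8)

    def test_wrong_input_rank_rejected(self):
        model = build_3dcbhga(tiny_3d_config(), n_mel=8)
        with pytest.raises(ValueError):
            model(np.zeros((2, 10, 8)))

    def test_conv_dims_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_3dcbhga(tiny_1d_config())
        with pytest.raises(ValueError):
            build_1dcbbg(tiny_3d_config(), input_length=10)


def _gradcheck(model, X, y, mask=None, n_entries=3, eps=1e-4,
               rtol=2e-3, atol=5e-4):
    """Central finite differences vs the analytic gradients."""
    rng = np.random.default_rng(0)

    def loss_val():
        return float(nn.softmax_cross_entropy(model(X, mask=mask), y).data)

    loss = nn.softmax_cross_entropy(model(X, mask=mask), y)
    loss.backward()
    for p in model.parameters():
        g = p.grad if p.grad is not None else np.zeros_like(p.data)
        flat = p.data.reshape(-1)
        for i in rng.choice(flat.size, size=min(n_entries, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss_val()
            flat[i] = orig - eps
            lm = loss_val()
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            np.testing.assert_allclose(g.reshape(-1)[i], num, rtol=rtol, atol=atol)


class TestGradients:
    def test_3d_model_gradients_match_finite_differences(self):
        model = build_3dcbhga(tiny_3d_config(), n_mel=6)
        for layer in model.modules():
            for name, v in vars(layer).items():
                if isinstance(v, nn.Tensor):
                    v.data = v.data.astype(np.float64)
        rng = np.random.default_rng(20)
        X = rng.normal(size=(2, 8, 6, 3))
        _gradcheck(model, X, np.array([0, 1]), mask=np.ones((2, 8), bool))

    def test_1d_model_gradients_match_finite_differences(self):
        model = build_1dcbbg(tiny_1d_config(), input_length=8, input_dim=5)
        for layer in model.modules():
            for name, v in vars(layer).items():
                if isinstance(v, nn.Tensor):
                    v.data = v.data.astype(np.float64)
        model.train_mode(True)  # exercise batch-norm's training path
        rng = np.random.default_rng(21)
        X = rng.normal(size=(3, 8, 5))
        _gradcheck(model, X, np.array([0, 1, 0]))
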