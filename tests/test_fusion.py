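"""Algebraic contracts of the five fusion operators and the classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connfusion.fusion import (FUSION_METHODS, FusionConfig, align,
                               attention_pool_combine, classify, cls_loss,
                               fuse, fuse_attention_pooling, fuse_bilinear,
                               fuse_concat, fuse_cross_attention, fuse_gated,
                               fused_dim, init_classifier, init_fusion)

D1, D2, DF = 10, 8, 6


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(0)


def make(method, **kw):
    cfg = FusionConfig(method=method, d_f=DF,
                       classifier_hidden=[8, 4, 2], **kw)
    params = init_fusion(np.random.default_rng(1), D1, D2, cfg)
    return cfg, params


class TestAlign:
    def test_output_lengths(self, rng):
        _, params = make("concat")
        h1t, h2t = align(params, rng.standard_normal(D1), rng.standard_normal(D2))
        assert h1t.shape == (DF,) and h2t.shape == (DF,)

    def test_zero_input_zero_bias(self):
        _, params = make("concat")
        params["W1"]["b"] *= 0.0
        h1t, _ = align(params, np.zeros(D1), np.zeros(D2))
        assert np.allclose(h1t, 0.0)

    def test_linearity_with_zero_bias(self, rng):
        _, params = make("concat")
        params["W1"]["b"] *= 0.0
        h1 = rng.standard_normal(D1)
        a1, _ = align(params, h1, np.zeros(D2))
        a2, _ = align(params, 3.0 * h1, np.zeros(D2))
        assert np.allclose(a2, 3.0 * a1, atol=1e-12)


class TestConcat:
    def test_halves_identity_and_swap(self, rng):
        h1t = rng.standard_normal(DF)
        h2t = rng.standard_normal(DF)
        out = fuse_concat(h1t, h2t)
        assert out.shape == (2 * DF,)
        assert np.array_equal(out[:DF], h1t)
        assert np.array_equal(out[DF:], h2t)
        swapped = fuse_concat(h2t, h1t)
        assert np.array_equal(swapped[:DF], h2t)


class TestGated:
    def test_gate_limits(self, rng):
        _, params = make("gated")
        h1, h2 = rng.standard_normal(D1), rng.standard_normal(D2)
        h1t, h2t = align(params, h1, h2)
        assert np.allclose(fuse_gated(params, h1, h2, h1t, h2t,
                                      gate_override=1.0), h1t)
        mid = fuse_gated(params, h1, h2, h1t, h2t, gate_override=0.5)
        assert np.allclose(mid, 0.5 * (h1t + h2t))

    def test_convexity_elementwise(self, rng):
        cfg, params = make("gated")
        h1, h2 = rng.standard_normal(D1), rng.standard_normal(D2)
        h1t, h2t = align(params, h1, h2)
        out = np.asarray(fuse_gated(params, h1, h2, h1t, h2t))
        lo = np.minimum(np.asarray(h1t), np.asarray(h2t))
        hi = np.maximum(np.asarray(h1t), np.asarray(h2t))
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)


class TestCrossAttention:
    def test_output_length(self, rng):
        cfg, params = make("cross_attention")
        h1t, h2t = rng.standard_normal(DF), rng.standard_normal(DF)
        assert fuse_cross_attention(params, h1t, h2t, cfg).shape == (DF,)

    def test_single_token_attention_weight_is_one(self, rng):
        """Softmax over a lone key is exactly 1, so the attended context is
        exactly the value projection of the other stream."""
        from connfusion._nn import functional as F
        cfg, params = make("cross_attention")
        h1t, h2t = rng.standard_normal(DF), rng.standard_normal(DF)
        c1_expected = F.linear(params["v_a"], h2t)
        # reproduce the attended output: residual-subtracted layer-norm input
        t1 = h1t[None]
        from connfusion.fusion import _cross_attn
        c1 = _cross_attn(params["q_a"], params["k_a"], params["v_a"],
                         h1t[None], h2t[None])[0]
        assert np.allclose(np.asarray(c1), np.asarray(c1_expected), atol=1e-12)

    def test_layer_norm_property_affine_disabled(self, rng):
        cfg, params = make("cross_attention")
        from connfusion._nn import functional as F
        import autograd.numpy as anp
        h1t, h2t = rng.standard_normal(DF), rng.standard_normal(DF)
        from connfusion.fusion import _cross_attn
        c1 = _cross_attn(params["q_a"], params["k_a"], params["v_a"],
                         h1t[None], h2t[None])[0]
        h1p = np.asarray(F.layer_norm(h1t + c1))
        assert abs(h1p.mean()) < 1e-4
        assert abs(h1p.var() - 1.0) < 1e-3

    def test_multi_token_mode_runs(self, rng):
        cfg, params = make("cross_attention", cross_attention_tokens=3)
        h1t, h2t = rng.standard_normal(DF), rng.standard_normal(DF)
        out = fuse_cross_attention(params, h1t, h2t, cfg)
        assert out.shape == (DF,) and np.all(np.isfinite(np.asarray(out)))


class TestBilinear:
    def test_zero_first_argument(self, rng):
        cfg, params = make("bilinear")
        h2 = rng.standard_normal(D2)
        h1t, h2t = align(params, np.zeros(D1), h2)
        out = fuse_bilinear(params, np.zeros(D1), h2, h1t, h2t, cfg)
        from connfusion._nn import functional as F
        want = F.layer_norm(np.asarray(h1t) + np.asarray(h2t),
                            params["ln"]["g"], params["ln"]["b"])
        assert np.allclose(np.asarray(out), np.asarray(want), atol=1e-12)

    def test_bilinearity_in_first_argument(self, rng):
        _, params = make("bilinear")
        params["c"] *= 0.0
        h1, h2 = rng.standard_normal(D1), rng.standard_normal(D2)
        bil = lambda a: np.einsum("i,kij,j->k", a, params["B"], h2)
        assert np.allclose(bil(2.5 * h1), 2.5 * bil(h1), atol=1e-6)

    def test_output_length_full_and_low_rank(self, rng):
        h1, h2 = rng.standard_normal(D1), rng.standard_normal(D2)
        for kw in ({}, {"bilinear_rank": 3}):
            cfg, params = make("bilinear", **kw)
            h1t, h2t = align(params, h1, h2)
            assert fuse_bilinear(params, h1, h2, h1t, h2t, cfg).shape == (DF,)


class TestAttentionPooling:
    def test_equal_logits_give_mean(self, rng):
        h1t, h2t = rng.standard_normal(DF), rng.standard_normal(DF)
        out = attention_pool_combine(h1t, h2t, np.array([1.3, 1.3]))
        assert np.allclose(np.asarray(out), 0.5 * (h1t + h2t), atol=1e-12)

    def test_softmax_saturation_returns_first_stream(self, rng):
        h1t, h2t = rng.standard_normal(DF), rng.standard_normal(DF)
        out = attention_pool_combine(h1t, h2t, np.array([20.0, -20.0]))
        assert np.allclose(np.asarray(out), h1t, atol=1e-6)

    def test_weights_sum_to_one_random_inputs(self, rng):
        from connfusion._nn import functional as F
        cfg, params = make("attention_pooling")
        for _ in range(10):
            h1t, h2t = rng.standard_normal(DF), rng.standard_normal(DF)
            logits = F.mlp(params["attn"], np.concatenate([h1t, h2t]))
            alpha = np.asarray(F.softmax(logits))
            assert alpha.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(alpha >= 0)

    def test_convex_combination_bounds(self, rng):
        cfg, params = make("attention_pooling")
        h1t, h2t = rng.standard_normal(DF), rng.standard_normal(DF)
        out = np.asarray(fuse_attention_pooling(params, h1t, h2t))
        lo = np.minimum(h1t, h2t)
        hi = np.maximum(h1t, h2t)
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)


class TestDispatchContract:
    @pytest.mark.parametrize("method", FUSION_METHODS)
    def test_all_methods_shared_contract(self, method, rng):
        cfg, params = make(method)
        h1 = rng.standard_normal((3, D1))
        h2 = rng.standard_normal((3, D2))
        out = np.asarray(fuse(params, h1, h2, cfg))
        assert out.shape == (3, fused_dim(cfg))
        assert np.all(np.isfinite(out))


class TestClassifier:
    def test_probabilities_sum_to_one_and_shape(self, rng):
        cfg, _ = make("concat")
        clf = init_classifier(np.random.default_rng(2), 2 * DF, cfg)
        fused = rng.standard_normal((4, 2 * DF))
        proba = np.asarray(classify(clf, fused))
        assert proba.shape == (4, 2)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-12)

    def test_deterministic_in_eval(self, rng):
        cfg, _ = make("concat")
        clf = init_classifier(np.random.default_rng(3), 2 * DF, cfg)
        fused = rng.standard_normal((2, 2 * DF))
        assert np.array_equal(np.asarray(classify(clf, fused)),
                              np.asarray(classify(clf, fused)))


class TestClsLoss:
    def test_uniform_prediction_log2(self):
        assert float(cls_loss(np.array([1]), np.array([[0.5, 0.5]]))) == \
            pytest.approx(np.log(2), abs=1e-9)

    def test_perfect_prediction_zero(self):
        assert float(cls_loss(np.array([0]), np.array([[1.0, 0.0]]))) == \
            pytest.approx(0.0, abs=1e-9)

    def test_confident_wrong_prediction(self):
        # true case predicted at 0.1 -> -log 0.1
        loss = float(cls_loss(np.array([1]), np.array([[0.9, 0.1]])))
        assert loss == pytest.approx(-np.log(0.1), abs=1e-9)

    def test_log_zero_guarded(self):
        loss = float(cls_loss(np.array([1]), np.array([[1.0, 0.0]])))
        assert np.isfinite(loss)


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=15, deadline=None)
def test_gated_and_pooling_outputs_always_convex(seed):
    rng = np.random.default_rng(seed)
    cfg_g, params_g = make("gated")
    h1, h2 = rng.standard_normal(D1), rng.standard_normal(D2)
    h1t, h2t = align(params_g, h1, h2)
    out = np.asarray(fuse_gated(params_g, h1, h2, h1t, h2t))
    lo = np.minimum(np.asarray(h1t), np.asarray(h2t))
    hi = np.maximum(np.asarray(h1t), np.asarray(h2t))
    assert np.all(out >= lo - 1e-10) and np.all(out <= hi + 1e-10)
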