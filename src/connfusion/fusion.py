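"""Fusion of the temporal and connectivity stream features, plus classifier.

All five fusion operators share one contract: they consume the raw stream
features ``h1`` (temporal) and ``h2`` (connectivity) together with their
linear alignments to a common dimension d_f

    h~1 = W1 h1 + b1,   h~2 = W2 h2 + b2

and return a single fused vector (length 2*d_f for ``concat``, d_f
otherwise) that feeds a three-layer softmax classifier.

Operators
---------
concat             [h~1; h~2]
gated              g = sigmoid(MLP([h1; h2])); g*h~1 + (1-g)*h~2
cross_attention    bidirectional single-token (or multi-token) cross
                   attention with residual + layer norm, then an MLP on the
                   concatenated normalised streams
bilinear           per-output bilinear form on raw h1, h2, plus the aligned
                   residual, layer-normalised
attention_pooling  alpha = softmax(MLP([h~1; h~2])) over the two streams;
                   alpha_1*h~1 + alpha_2*h~2

The gate input and the bilinear arguments use the *raw* features, while the
combination paths use the aligned ones, following the operator definitions
literally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import autograd.numpy as anp
import numpy as onp

from ._nn import functional as F

__all__ = ["FusionConfig", "FUSION_METHODS", "init_fusion", "align",
           "fuse_concat", "fuse_gated", "fuse_cross_attention",
           "fuse_bilinear", "fuse_attention_pooling", "attention_pool_combine",
           "fuse", "fused_dim",
           "init_classifier", "classify", "classifier_logits", "cls_loss"]

FUSION_METHODS = ("concat", "gated", "cross_attention", "bilinear",
                  "attention_pooling")


@dataclass
class FusionConfig:
    method: str = "attention_pooling"
    d_f: int = 128
    classifier_hidden: List[int] = field(default_factory=lambda: [256, 64, 2])
    dropout: float = 0.3
    cross_attention_tokens: int = 1    # 1 = single-token mode; >1 reshapes
    bilinear_rank: Optional[int] = None  # None = full bilinear tensor

    def __post_init__(self):
        if self.method not in FUSION_METHODS:
            raise ValueError(f"unknown fusion method {self.method!r}")
        if self.d_f <= 0:
            raise ValueError("d_f must be positive")
        if self.classifier_hidden[-1] != 2:
            raise ValueError("classifier output size must be 2")
        if self.method == "cross_attention" and self.d_f % self.cross_attention_tokens:
            raise ValueError("d_f must be divisible by cross_attention_tokens")


def fused_dim(cfg: FusionConfig) -> int:
    return 2 * cfg.d_f if cfg.method == "concat" else cfg.d_f


def init_fusion(rng, d1: int, d2: int, cfg: FusionConfig):
    """Parameters for the alignment maps plus the chosen operator."""
    p = {"W1": F.init_linear(rng, d1, cfg.d_f),
         "W2": F.init_linear(rng, d2, cfg.d_f)}
    if cfg.method == "gated":
        p["gate"] = F.init_mlp(rng, [d1 + d2, cfg.d_f, cfg.d_f])
    elif cfg.method == "cross_attention":
        dt = cfg.d_f // cfg.cross_attention_tokens
        for stream in ("a", "b"):
            p[f"q_{stream}"] = F.init_linear(rng, dt, dt)
            p[f"k_{stream}"] = F.init_linear(rng, dt, dt)
            p[f"v_{stream}"] = F.init_linear(rng, dt, dt)
        p["ln1"] = F.init_layer_norm(cfg.d_f)
        p["ln2"] = F.init_layer_norm(cfg.d_f)
        p["mix"] = F.init_mlp(rng, [2 * cfg.d_f, cfg.d_f, cfg.d_f])
    elif cfg.method == "bilinear":
        if cfg.bilinear_rank is None:
            scale = 1.0 / onp.sqrt(d1 * d2)
            p["B"] = rng.standard_normal((cfg.d_f, d1, d2)) * scale
            p["c"] = onp.zeros(cfg.d_f)
        else:
            r = cfg.bilinear_rank
            p["U"] = F.init_linear(rng, d1, r)
            p["V"] = F.init_linear(rng, d2, r)
            p["P"] = F.init_linear(rng, r, cfg.d_f)
        p["ln"] = F.init_layer_norm(cfg.d_f)
    elif cfg.method == "attention_pooling":
        p["attn"] = F.init_mlp(rng, [2 * cfg.d_f, cfg.d_f, 2])
    return p


def align(params, h1, h2):
    """Linear maps of both streams to the common dimension d_f."""
    return F.linear(params["W1"], h1), F.linear(params["W2"], h2)


def fuse_concat(h1t, h2t):
    return anp.concatenate([h1t, h2t], axis=-1)


def fuse_gated(params, h1, h2, h1t, h2t, gate_override=None):
    """Element-wise convex combination with a learned sigmoid gate.

    ``gate_override`` substitutes an explicit gate value (scalar or vector),
    used to check the operator's limits.
    """
    if gate_override is None:
        g = F.sigmoid(F.mlp(params["gate"], anp.concatenate([h1, h2], axis=-1)))
    else:
        g = gate_override
    return g * h1t + (1.0 - g) * h2t


def _cross_attn(q_p, k_p, v_p, query_tokens, key_tokens):
    """softmax(QK^T / sqrt(d)) V over token axes (..., S, d)."""
    q = F.linear(q_p, query_tokens)
    k = F.linear(k_p, key_tokens)
    v = F.linear(v_p, key_tokens)
    d = q.shape[-1]
    attn = F.softmax(q @ anp.swapaxes(k, -1, -2) / anp.sqrt(float(d)))
    return attn @ v


def fuse_cross_attention(params, h1t, h2t, cfg: FusionConfig,
                         affine_ln: bool = True):
    """Bidirectional cross-attention + residual + layer norm + mixing MLP.

    In single-token mode each aligned vector is one token, so the softmax
    over the lone key is exactly 1; ``cross_attention_tokens > 1`` reshapes
    each vector into that many sub-tokens to make attention non-trivial.
    """
    nt = cfg.cross_attention_tokens
    dt = cfg.d_f // nt
    lead = h1t.shape[:-1]
    t1 = anp.reshape(h1t, lead + (nt, dt))
    t2 = anp.reshape(h2t, lead + (nt, dt))
    c1 = anp.reshape(_cross_attn(params["q_a"], params["k_a"], params["v_a"], t1, t2),
                     lead + (cfg.d_f,))
    c2 = anp.reshape(_cross_attn(params["q_b"], params["k_b"], params["v_b"], t2, t1),
                     lead + (cfg.d_f,))
    if affine_ln:
        h1p = F.layer_norm(h1t + c1, params["ln1"]["g"], params["ln1"]["b"])
        h2p = F.layer_norm(h2t + c2, params["ln2"]["g"], params["ln2"]["b"])
    else:
        h1p = F.layer_norm(h1t + c1)
        h2p = F.layer_norm(h2t + c2)
    return F.mlp(params["mix"], anp.concatenate([h1p, h2p], axis=-1))


def fuse_bilinear(params, h1, h2, h1t, h2t, cfg: FusionConfig = None):
    """Bilinear interaction on raw features + aligned residual, layer-normed."""
    if "B" in params:
        bil = anp.einsum("...i,kij,...j->...k", h1, params["B"], h2) + params["c"]
    else:
        bil = F.linear(params["P"],
                       F.linear(params["U"], h1) * F.linear(params["V"], h2))
    return F.layer_norm(bil + (h1t + h2t), params["ln"]["g"], params["ln"]["b"])


def attention_pool_combine(h1t, h2t, logits):
    """Convex combination of the two streams from two attention logits."""
    alpha = F.softmax(logits, axis=-1)
    a1 = alpha[..., 0:1]
    a2 = alpha[..., 1:2]
    return a1 * h1t + a2 * h2t


def fuse_attention_pooling(params, h1t, h2t, logits_override=None):
    if logits_override is None:
        logits = F.mlp(params["attn"], anp.concatenate([h1t, h2t], axis=-1))
    else:
        logits = logits_override
    return attention_pool_combine(h1t, h2t, logits)


def fuse(params, h1, h2, cfg: FusionConfig):
    """Dispatch to the configured operator; returns the fused feature."""
    h1t, h2t = align(params, h1, h2)
    if cfg.method == "concat":
        return fuse_concat(h1t, h2t)
    if cfg.method == "gated":
        return fuse_gated(params, h1, h2, h1t, h2t)
    if cfg.method == "cross_attention":
        return fuse_cross_attention(params, h1t, h2t, cfg)
    if cfg.method == "bilinear":
        return fuse_bilinear(params, h1, h2, h1t, h2t, cfg)
    return fuse_attention_pooling(params, h1t, h2t)


# ---------------------------------------------------------------------------
# Classification head
# ---------------------------------------------------------------------------

def init_classifier(rng, in_dim: int, cfg: FusionConfig):
    return F.init_mlp(rng, [in_dim] + list(cfg.classifier_hidden))


def classifier_logits(params, fused, drop_masks=None):
    return F.mlp(params, fused, drop_masks)


def classify(params, fused):
    """Class probabilities (control, case); rows sum to 1."""
    return F.softmax(classifier_logits(params, fused), axis=-1)


def cls_loss(y, y_prob, eps: float = 1e-12):
    """Cross-entropy -sum_i y_i log(p_i) with an epsilon guard, averaged
    over the batch.  ``y`` is an integer label array (0/1)."""
    y = onp.atleast_1d(onp.asarray(y))
    p = anp.atleast_2d(y_prob)
    idx = onp.arange(y.size)
    return -anp.mean(anp.log(p[idx, y] + eps))
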