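"""Functional neural-network primitives on autograd-traceable numpy.

Parameters are nested dicts/lists of ``numpy`` arrays ("pytrees"); every
forward function is a pure function of ``(params, inputs)`` so that
:func:`autograd.grad` can differentiate end to end.  All shapes are batched:
sequence inputs are ``(B, S, d)``.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as onp

__all__ = [
    "glorot",
    "linear",
    "relu",
    "sigmoid",
    "softmax",
    "log_softmax",
    "layer_norm",
    "sinusoidal_encoding",
    "init_linear",
    "init_layer_norm",
    "init_mlp",
    "mlp",
    "init_encoder_layer",
    "encoder_layer",
    "init_encoder_stack",
    "encoder_stack",
    "dropout_mask",
]


def glorot(rng: onp.random.Generator, fan_in: int, fan_out: int) -> onp.ndarray:
    """Glorot/Xavier uniform initialisation for a (fan_in, fan_out) weight."""
    limit = onp.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_linear(rng, d_in, d_out):
    return {"W": glorot(rng, d_in, d_out), "b": onp.zeros(d_out)}


def linear(p, x):
    return x @ p["W"] + p["b"]


def relu(x):
    return anp.maximum(0.0, x)


def sigmoid(x):
    return 1.0 / (1.0 + anp.exp(-x))


def softmax(x, axis=-1):
    x = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(x)
    return e / anp.sum(e, axis=axis, keepdims=True)


def log_softmax(x, axis=-1):
    x = x - anp.max(x, axis=axis, keepdims=True)
    return x - anp.log(anp.sum(anp.exp(x), axis=axis, keepdims=True))


def layer_norm(x, gain=None, bias=None, eps=1e-5):
    """Normalise the trailing axis to zero mean / unit variance.

    ``gain``/``bias`` apply the optional learned affine; passing ``None``
    leaves the normalised values untouched (used by tests that check the
    normalisation property itself).
    """
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.var(x, axis=-1, keepdims=True)
    out = (x - mu) / anp.sqrt(var + eps)
    if gain is not None:
        out = out * gain
    if bias is not None:
        out = out + bias
    return out


def init_layer_norm(d):
    return {"g": onp.ones(d), "b": onp.zeros(d)}


def sinusoidal_encoding(n_positions: int, d_model: int) -> onp.ndarray:
    """Classic fixed sin/cos positional table, shape (n_positions, d_model).

    Computed analytically per call, so sequences of any length are supported
    without re-instantiating a model.
    """
    pos = onp.arange(n_positions)[:, None].astype(float)
    i = onp.arange(d_model)[None, :]
    angle = pos / onp.power(10000.0, (2 * (i // 2)) / d_model)
    enc = onp.where(i % 2 == 0, onp.sin(angle), onp.cos(angle))
    return enc


def init_mlp(rng, dims):
    """Fully-connected stack; ReLU between layers, none after the last."""
    return [init_linear(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]


def mlp(p, x, drop_masks=None):
    for k, layer in enumerate(p):
        x = linear(layer, x)
        if k < len(p) - 1:
            x = relu(x)
            if drop_masks is not None:
                x = x * drop_masks[k]
    return x


def dropout_mask(rng: onp.random.Generator, shape, rate: float) -> onp.ndarray:
    """Inverted-dropout keep mask drawn outside the autograd trace."""
    if rate <= 0.0:
        return onp.ones(shape)
    keep = (rng.random(shape) >= rate).astype(float)
    return keep / (1.0 - rate)


# ---------------------------------------------------------------------------
# Transformer encoder (post-LN, as in the original architecture)
# ---------------------------------------------------------------------------

def init_encoder_layer(rng, d_model, ff_dim):
    return {
        "qkv": init_linear(rng, d_model, 3 * d_model),
        "out": init_linear(rng, d_model, d_model),
        "ln1": init_layer_norm(d_model),
        "ff1": init_linear(rng, d_model, ff_dim),
        "ff2": init_linear(rng, ff_dim, d_model),
        "ln2": init_layer_norm(d_model),
    }


def _self_attention(p, h, n_heads):
    B, S, d = h.shape[0], h.shape[1], h.shape[2]
    dh = d // n_heads
    qkv = linear(p["qkv"], h)
    q, k, v = qkv[..., :d], qkv[..., d:2 * d], qkv[..., 2 * d:]

    def heads(z):
        return anp.transpose(anp.reshape(z, (B, S, n_heads, dh)), (0, 2, 1, 3))

    q, k, v = heads(q), heads(k), heads(v)
    scores = q @ anp.transpose(k, (0, 1, 3, 2)) / anp.sqrt(float(dh))
    attn = softmax(scores, axis=-1)
    ctx = anp.reshape(anp.transpose(attn @ v, (0, 2, 1, 3)), (B, S, d))
    return linear(p["out"], ctx)


def encoder_layer(p, h, n_heads, drop=None):
    """One post-LN block: MHSA + residual + LN, then FF + residual + LN.

    ``drop`` is an optional pair of pre-drawn inverted-dropout masks for the
    attention and feed-forward sublayer outputs.
    """
    a = _self_attention(p, h, n_heads)
    if drop is not None:
        a = a * drop[0]
    h = layer_norm(h + a, p["ln1"]["g"], p["ln1"]["b"])
    f = linear(p["ff2"], relu(linear(p["ff1"], h)))
    if drop is not None:
        f = f * drop[1]
    h = layer_norm(h + f, p["ln2"]["g"], p["ln2"]["b"])
    return h


def init_encoder_stack(rng, n_layers, d_model, ff_dim):
    return [init_encoder_layer(rng, d_model, ff_dim) for _ in range(n_layers)]


def encoder_stack(p, h, n_heads, drops=None):
    for k, layer in enumerate(p):
        h = encoder_layer(layer, h, n_heads, None if drops is None else drops[k])
    return h
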