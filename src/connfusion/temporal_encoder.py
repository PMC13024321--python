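"""Temporal-stream Transformer over raw ROI time series.

Each time point (an R-vector of ROI values) is linearly projected to the
model dimension, sinusoidal positional encodings are added, a learnable
[CLS] token is prepended, and the sequence runs through post-LN Transformer
encoder layers.  The subject embedding ``h1`` is the [CLS] output.

Self-supervised pre-training masks whole time-point rows (a per-batch ratio
drawn uniformly from ``mask_ratio_range``), replaces them with a learned
mask token *before* the input projection, and trains a linear decoder to
reconstruct the original values; the MSE is taken over masked entries only,
i.e. all R ROI values of every masked row.  A ``mask_granularity="cell"``
option instead masks individual (t, r) cells at the mean of the ratio range,
for the alternative reading of "mask a percentage of the input".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import autograd.numpy as anp
import numpy as onp
from autograd import grad

from ._nn import functional as F
from ._nn.optim import Adam

__all__ = ["TemporalEncoderConfig", "MaskSpec", "init_temporal_encoder",
           "encode_roi", "sample_mask", "apply_row_mask", "reconstruct_roi",
           "roi_recon_loss", "sample_cell_mask", "roi_recon_loss_cells",
           "pretrain_temporal"]


@dataclass
class TemporalEncoderConfig:
    """Architecture + pretext-task settings for the temporal stream.

    Defaults are the full-scale configuration (512-dim, 6 layers, 8 heads,
    feed-forward 2048, dropout 0.1, mask ratio drawn from [0.25, 0.5]).
    """

    n_rois: int = 200
    d1: int = 512
    L1: int = 6
    heads: int = 8
    ff_dim: int = 2048
    dropout: float = 0.1
    mask_ratio_range: Tuple[float, float] = (0.25, 0.5)
    mask_granularity: str = "row"      # "row" (default) or "cell"
    mask_token: str = "learned"        # "learned" or "zero"

    def __post_init__(self):
        if self.d1 % self.heads != 0:
            raise ValueError("d1 must be divisible by heads")
        lo, hi = self.mask_ratio_range
        if not (0 < lo <= hi < 1):
            raise ValueError("mask_ratio_range must satisfy 0 < low <= high < 1")
        if self.mask_granularity not in ("row", "cell"):
            raise ValueError("mask_granularity must be 'row' or 'cell'")


@dataclass(frozen=True)
class MaskSpec:
    """Masked time-point rows for one pretext batch."""

    masked_rows: tuple
    seed: int
    ratio: float

    def __post_init__(self):
        if len(self.masked_rows) == 0:
            raise ValueError("mask must be non-empty")


def init_temporal_encoder(rng: onp.random.Generator, cfg: TemporalEncoderConfig):
    return {
        "in_proj": F.init_linear(rng, cfg.n_rois, cfg.d1),
        "cls": rng.standard_normal(cfg.d1) * 0.02,
        "mask_tok": rng.standard_normal(cfg.n_rois) * 0.02,
        "layers": F.init_encoder_stack(rng, cfg.L1, cfg.d1, cfg.ff_dim),
        "decoder": F.init_linear(rng, cfg.d1, cfg.n_rois),
    }


def _encode_tokens(params, X, cfg: TemporalEncoderConfig, drops=None):
    """Shared trunk: returns all token outputs, shape (B, T+1, d1)."""
    B, T = X.shape[0], X.shape[1]
    h = F.linear(params["in_proj"], X)                       # (B, T, d1)
    h = h + F.sinusoidal_encoding(T, cfg.d1)[None, :, :]
    cls = anp.broadcast_to(anp.reshape(params["cls"], (1, 1, cfg.d1)),
                           (B, 1, cfg.d1))
    h = anp.concatenate([cls, h], axis=1)
    return F.encoder_stack(params["layers"], h, cfg.heads, drops)


def encode_roi(params, series, cfg: TemporalEncoderConfig, drops=None):
    """Subject embedding(s) ``h1``: [CLS] output, shape (B, d1) or (d1,)."""
    single = onp.ndim(series) == 2
    X = series[None] if single else series
    if X.shape[2] != cfg.n_rois:
        raise ValueError(f"expected R={cfg.n_rois} ROI columns, got {X.shape[2]}")
    h = _encode_tokens(params, X, cfg, drops)[:, 0, :]
    return h[0] if single else h


def sample_mask(T: int, cfg: TemporalEncoderConfig, seed: int) -> MaskSpec:
    """Draw a per-call mask ratio uniformly and sample rows w/o replacement."""
    if T < 4:
        raise ValueError("need T >= 4 to mask time points")
    rng = onp.random.default_rng(seed)
    lo, hi = cfg.mask_ratio_range
    ratio = float(rng.uniform(lo, hi))
    n_mask = max(1, int(round(ratio * T)))
    rows = rng.choice(T, size=n_mask, replace=False)
    return MaskSpec(tuple(sorted(int(r) for r in rows)), seed, ratio)


def apply_row_mask(params, X, mask: MaskSpec, cfg: TemporalEncoderConfig):
    """Replace masked rows by the mask token (or zeros) before projection."""
    rows = onp.array(mask.masked_rows)
    if rows.max() >= X.shape[-2]:
        raise ValueError("mask indices out of range")
    keep = onp.ones((X.shape[-2], 1))
    keep[rows] = 0.0
    token = params["mask_tok"] if cfg.mask_token == "learned" else anp.zeros(cfg.n_rois)
    return X * keep + (1.0 - keep) * token


def reconstruct_roi(params, series_masked, mask: MaskSpec,
                    cfg: TemporalEncoderConfig, drops=None):
    """Decode every non-CLS token back to R ROI values, shape like the input."""
    single = onp.ndim(series_masked) == 2
    X = series_masked[None] if single else series_masked
    rows = onp.array(mask.masked_rows)
    if rows.max() >= X.shape[1]:
        raise ValueError("mask indices out of range")
    tokens = _encode_tokens(params, X, cfg, drops)[:, 1:, :]
    out = F.linear(params["decoder"], tokens)
    return out[0] if single else out


def roi_recon_loss(x, x_hat, mask: MaskSpec):
    """MSE over masked entries only: mean over {(t, r) : t masked, all r}."""
    rows = onp.array(mask.masked_rows)
    if rows.size == 0:
        raise ValueError("empty mask")
    diff = x_hat - x
    sel = diff[..., rows, :]
    return anp.mean(sel ** 2)


def sample_cell_mask(T: int, R: int, ratio: float, seed: int) -> onp.ndarray:
    """Boolean (T, R) mask of individual cells, round(ratio*T*R) of them."""
    rng = onp.random.default_rng(seed)
    n_mask = max(1, int(round(ratio * T * R)))
    flat = rng.choice(T * R, size=n_mask, replace=False)
    m = onp.zeros(T * R, dtype=bool)
    m[flat] = True
    return m.reshape(T, R)


def roi_recon_loss_cells(x, x_hat, cell_mask: onp.ndarray):
    """MSE over an explicit set of masked (t, r) cells."""
    if not cell_mask.any():
        raise ValueError("empty mask")
    w = cell_mask.astype(float)
    return anp.sum(((x_hat - x) * w) ** 2) / (w.sum() * (1 if x.ndim == 2 else x.shape[0]))


def _masked_batch_loss(params, X, mask, cfg, drops=None):
    if isinstance(mask, MaskSpec):
        Xm = apply_row_mask(params, X, mask, cfg)
        Xh = reconstruct_roi(params, Xm, mask, cfg, drops)
        return roi_recon_loss(X, Xh, mask)
    # cell granularity: mask is a boolean (T, R) matrix
    token = params["mask_tok"] if cfg.mask_token == "learned" else anp.zeros(cfg.n_rois)
    w = mask.astype(float)
    Xm = X * (1.0 - w) + w * token
    tokens = _encode_tokens(params, Xm[None] if X.ndim == 2 else Xm, cfg, drops)[:, 1:, :]
    Xh = F.linear(params["decoder"], tokens)
    if X.ndim == 2:
        Xh = Xh[0]
    return roi_recon_loss_cells(X, Xh, mask)


def pretrain_temporal(params, X_train, X_val, cfg: TemporalEncoderConfig,
                      epochs: int = 100, batch_size: int = 32, lr: float = 1e-4,
                      weight_decay: float = 1e-4, seed: int = 0, verbose=False):
    """Masked-reconstruction pre-training loop.

    Returns ``(params, history)`` where history has per-epoch train/val
    losses.  Validation uses a fixed mask (drawn once from ``seed``) so the
    curve is comparable across epochs.
    """
    rng = onp.random.default_rng(seed)
    T = X_train.shape[1]
    opt = Adam({"enc": params}, lr=lr, weight_decay=weight_decay)
    tree = {"enc": params}
    if cfg.mask_granularity == "row":
        val_mask = sample_mask(T, cfg, seed=int(rng.integers(2 ** 31)))
    else:
        val_mask = sample_cell_mask(T, cfg.n_rois,
                                    float(onp.mean(cfg.mask_ratio_range)),
                                    seed=int(rng.integers(2 ** 31)))
    history = {"train": [], "val": []}
    n = X_train.shape[0]
    loss_grad = grad(lambda p, X, m, d: _masked_batch_loss(p, X, m, cfg, d))
    for epoch in range(epochs):
        order = rng.permutation(n)
        ep_losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            Xb = X_train[idx]
            if cfg.mask_granularity == "row":
                mask = sample_mask(T, cfg, seed=int(rng.integers(2 ** 31)))
            else:
                ratio = float(onp.mean(cfg.mask_ratio_range))
                mask = sample_cell_mask(T, cfg.n_rois, ratio,
                                        seed=int(rng.integers(2 ** 31)))
            drops = _draw_drops(rng, cfg, Xb.shape[0], T + 1) if cfg.dropout > 0 else None
            g = loss_grad(tree["enc"], Xb, mask, drops)
            ep_losses.append(float(_masked_batch_loss(tree["enc"], Xb, mask, cfg, drops)))
            tree = opt.step(tree, {"enc": g})
        val_loss = float(_masked_batch_loss(tree["enc"], X_val, val_mask, cfg))
        history["train"].append(float(onp.mean(ep_losses)))
        history["val"].append(val_loss)
        if verbose:
            print(f"[temporal pretrain] epoch {epoch + 1}: "
                  f"train {history['train'][-1]:.4f} val {val_loss:.4f}")
    return tree["enc"], history


def _draw_drops(rng, cfg, B, S):
    return [(F.dropout_mask(rng, (B, S, cfg.d1), cfg.dropout),
             F.dropout_mask(rng, (B, S, cfg.d1), cfg.dropout))
            for _ in range(cfg.L1)]
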