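"""Connectivity-stream Transformer over the flattened Pearson vector.

The length-D connectivity vector (strict upper triangle of the correlation
matrix, D = R(R-1)/2) is cut into fixed-length patches, each patch is
linearly embedded, sinusoidal positional encodings are added, and the patch
sequence runs through post-LN encoder layers.  The subject embedding ``h2``
is the layer-normalised mean over patch outputs.

Pre-training masks a fixed fraction ``m2`` of vector elements (set to zero —
the natural null correlation — before patch embedding, or replaced by a
learned scalar token via ``mask_token="learned"``) and reconstructs them
with a per-patch linear head; the MSE runs over masked, non-padded
positions only.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as onp
from autograd import grad

from ._nn import functional as F
from ._nn.optim import Adam

__all__ = ["ConnectivityEncoderConfig", "init_connectivity_encoder",
           "patchify", "depatchify", "pad_mask", "encode_pcc",
           "sample_pcc_mask", "pcc_recon_loss", "joint_pretrain_loss",
           "reconstruct_pcc", "pretrain_connectivity"]


@dataclass
class ConnectivityEncoderConfig:
    """Architecture + pretext settings for the connectivity stream.

    Defaults are the full-scale configuration: 256-dim, 2 layers, 8 heads,
    feed-forward 512, 100 elements per patch (199 patches for a 200-ROI
    atlas, no padding), mask ratio 0.15.
    """

    D: int = 19900
    d2: int = 256
    L2: int = 2
    heads: int = 8
    ff_dim: int = 512
    dropout: float = 0.1
    patch_len: int = 100
    m2: float = 0.15
    mask_token: str = "zero"          # "zero" (default) or "learned"

    def __post_init__(self):
        if self.d2 % self.heads != 0:
            raise ValueError("d2 must be divisible by heads")
        if self.patch_len < 1:
            raise ValueError("patch_len must be >= 1")
        if not (0 < self.m2 < 1):
            raise ValueError("m2 must be in (0, 1)")

    @property
    def n_patches(self) -> int:
        return -(-self.D // self.patch_len)      # ceil division

    @property
    def n_pad(self) -> int:
        return self.n_patches * self.patch_len - self.D


def init_connectivity_encoder(rng: onp.random.Generator,
                              cfg: ConnectivityEncoderConfig):
    return {
        "patch_embed": F.init_linear(rng, cfg.patch_len, cfg.d2),
        "mask_tok": rng.standard_normal(1) * 0.02,
        "layers": F.init_encoder_stack(rng, cfg.L2, cfg.d2, cfg.ff_dim),
        "out_ln": F.init_layer_norm(cfg.d2),
        "decoder": F.init_linear(rng, cfg.d2, cfg.patch_len),
    }


def patchify(vec, cfg: ConnectivityEncoderConfig):
    """Cut (..., D) into (..., N, patch_len), zero-padding the final patch."""
    vec = anp.asarray(vec) if not hasattr(vec, "ndim") else vec
    lead = vec.shape[:-1]
    if vec.shape[-1] != cfg.D:
        raise ValueError(f"expected vector length {cfg.D}, got {vec.shape[-1]}")
    if cfg.n_pad:
        pad = anp.zeros(lead + (cfg.n_pad,))
        vec = anp.concatenate([vec, pad], axis=-1)
    return anp.reshape(vec, lead + (cfg.n_patches, cfg.patch_len))


def depatchify(patches, cfg: ConnectivityEncoderConfig):
    """Exact inverse of :func:`patchify` (padding discarded)."""
    lead = patches.shape[:-2]
    flat = anp.reshape(patches, lead + (cfg.n_patches * cfg.patch_len,))
    return flat[..., :cfg.D]


def pad_mask(cfg: ConnectivityEncoderConfig) -> onp.ndarray:
    """Boolean length-(N*patch_len) vector, True at real (non-pad) positions."""
    m = onp.zeros(cfg.n_patches * cfg.patch_len, dtype=bool)
    m[:cfg.D] = True
    return m


def _patch_tokens(params, vec, cfg, drops=None):
    patches = patchify(vec, cfg)
    h = F.linear(params["patch_embed"], patches)
    h = h + F.sinusoidal_encoding(cfg.n_patches, cfg.d2)[None, :, :]
    return F.encoder_stack(params["layers"], h, cfg.heads, drops)


def encode_pcc(params, vec, cfg: ConnectivityEncoderConfig, drops=None,
               affine_out: bool = True):
    """Subject embedding(s) ``h2``: mean-pooled, layer-normalised patch output.

    ``affine_out=False`` disables the learned affine of the final layer norm
    (used by tests that check the normalisation property itself).
    """
    single = onp.ndim(vec) == 1
    V = vec[None] if single else vec
    tokens = _patch_tokens(params, V, cfg, drops)
    pooled = anp.mean(tokens, axis=1)
    if affine_out:
        h = F.layer_norm(pooled, params["out_ln"]["g"], params["out_ln"]["b"])
    else:
        h = F.layer_norm(pooled)
    return h[0] if single else h


def sample_pcc_mask(D: int, m2: float, seed: int) -> onp.ndarray:
    """round(m2*D) distinct element indices, deterministic given seed."""
    if not (0 < m2 < 1):
        raise ValueError("m2 must be in (0, 1)")
    rng = onp.random.default_rng(seed)
    n_mask = max(1, int(round(m2 * D)))
    return onp.sort(rng.choice(D, size=n_mask, replace=False))


def pcc_recon_loss(p, p_hat, mask_idx):
    """MSE over masked positions only (padding never enters: indices < D)."""
    mask_idx = onp.asarray(mask_idx)
    if mask_idx.size == 0:
        raise ValueError("empty mask")
    diff = (p_hat - p)[..., mask_idx]
    return anp.mean(diff ** 2)


def joint_pretrain_loss(l_roi, l_pcc, lam: float = 1.0):
    """Combined pretext objective: temporal MSE + lam * connectivity MSE."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return l_roi + lam * l_pcc


def reconstruct_pcc(params, vec_masked, cfg: ConnectivityEncoderConfig,
                    drops=None):
    """Decode every patch token back to patch_len values; returns (..., D)."""
    single = onp.ndim(vec_masked) == 1
    V = vec_masked[None] if single else vec_masked
    tokens = _patch_tokens(params, V, cfg, drops)
    out = depatchify(F.linear(params["decoder"], tokens), cfg)
    return out[0] if single else out


def _masked_batch_loss(params, P, mask_idx, cfg, drops=None):
    keep = onp.ones(cfg.D)
    keep[mask_idx] = 0.0
    if cfg.mask_token == "learned":
        Pm = P * keep + (1.0 - keep) * params["mask_tok"][0]
    else:
        Pm = P * keep
    Ph = reconstruct_pcc(params, Pm, cfg, drops)
    return pcc_recon_loss(P, Ph, mask_idx)


def pretrain_connectivity(params, P_train, P_val, cfg: ConnectivityEncoderConfig,
                          epochs: int = 100, batch_size: int = 32, lr: float = 1e-4,
                          weight_decay: float = 1e-4, seed: int = 0, verbose=False):
    """Masked-element reconstruction pre-training; returns (params, history)."""
    rng = onp.random.default_rng(seed)
    opt = Adam({"enc": params}, lr=lr, weight_decay=weight_decay)
    tree = {"enc": params}
    val_mask = sample_pcc_mask(cfg.D, cfg.m2, seed=int(rng.integers(2 ** 31)))
    history = {"train": [], "val": []}
    n = P_train.shape[0]
    loss_grad = grad(lambda p, P, m, d: _masked_batch_loss(p, P, m, cfg, d))
    for epoch in range(epochs):
        order = rng.permutation(n)
        ep_losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            Pb = P_train[idx]
            mask = sample_pcc_mask(cfg.D, cfg.m2, seed=int(rng.integers(2 ** 31)))
            drops = _draw_drops(rng, cfg, Pb.shape[0]) if cfg.dropout > 0 else None
            g = loss_grad(tree["enc"], Pb, mask, drops)
            ep_losses.append(float(_masked_batch_loss(tree["enc"], Pb, mask, cfg, drops)))
            tree = opt.step(tree, {"enc": g})
        val_loss = float(_masked_batch_loss(tree["enc"], P_val, val_mask, cfg))
        history["train"].append(float(onp.mean(ep_losses)))
        history["val"].append(val_loss)
        if verbose:
            print(f"[connectivity pretrain] epoch {epoch + 1}: "
                  f"train {history['train'][-1]:.4f} val {val_loss:.4f}")
    return tree["enc"], history


def _draw_drops(rng, cfg, B):
    S = cfg.n_patches
    return [(F.dropout_mask(rng, (B, S, cfg.d2), cfg.dropout),
             F.dropout_mask(rng, (B, S, cfg.d2), cfg.dropout))
            for _ in range(cfg.L2)]
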