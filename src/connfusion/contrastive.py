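"""Contrastive alignment of the two streams' features.

Each stream gets its own projection head — a two-layer perceptron
(in -> hidden -> out with one ReLU) whose output is L2-normalised onto the
unit sphere.  The temporal projection of one subject and the connectivity
projection of the *same* subject form a positive pair; all other in-batch
connectivity projections are negatives.  The temperature-scaled InfoNCE
objective (denominator over all in-batch candidates, positive included) is
minimised; by default both retrieval directions (temporal->connectivity and
connectivity->temporal) are averaged, with ``direction="t2p"`` giving the
one-directional form.

Encoder freezing is expressed by a :class:`FreezePolicy`; frozen encoders'
parameters are bit-identical before and after the stage while the heads are
always trained.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as onp
from autograd import grad

from ._nn import functional as F
from ._nn.optim import Adam, tree_copy
from .connectivity_encoder import ConnectivityEncoderConfig, encode_pcc
from .temporal_encoder import TemporalEncoderConfig, encode_roi

__all__ = ["ProjectionHeadConfig", "FreezePolicy", "init_projection_head",
           "project", "infonce_loss", "run_contrastive_stage",
           "alignment_metrics"]


@dataclass
class ProjectionHeadConfig:
    in_dim: int
    hidden: int = 256
    out_dim: int = 128

    def __post_init__(self):
        if min(self.in_dim, self.hidden, self.out_dim) <= 0:
            raise ValueError("all projection dims must be positive")


@dataclass
class FreezePolicy:
    """Which encoders stay fixed during a training stage."""

    freeze_tst1: bool = False
    freeze_tst2: bool = False

    @classmethod
    def from_name(cls, name: str) -> "FreezePolicy":
        table = {"both": (True, True), "tst1": (True, False),
                 "tst2": (False, True), "none": (False, False)}
        if name not in table:
            raise ValueError(f"unknown freeze policy {name!r}; use {sorted(table)}")
        return cls(*table[name])

    def frozen_modules(self) -> set:
        out = set()
        if self.freeze_tst1:
            out.add("tst1")
        if self.freeze_tst2:
            out.add("tst2")
        return out


def init_projection_head(rng, cfg: ProjectionHeadConfig):
    return {"fc1": F.init_linear(rng, cfg.in_dim, cfg.hidden),
            "fc2": F.init_linear(rng, cfg.hidden, cfg.out_dim)}


def project(params, h, eps: float = 1e-12):
    """Head forward + L2 normalisation; never NaN (epsilon-guarded norm)."""
    z = F.linear(params["fc2"], F.relu(F.linear(params["fc1"], h)))
    norm = anp.sqrt(anp.sum(z ** 2, axis=-1, keepdims=True) + eps ** 2)
    return z / norm


def infonce_loss(z_t, z_p, tau: float = 0.07, direction: str = "symmetric"):
    """Temperature-scaled in-batch contrastive loss over unit vectors.

    ``z_t``/``z_p`` are (N, m) matched rows.  Per anchor t_i the loss is
    -log softmax_i(sim(t_i, p_j)/tau) at j = i, averaged over anchors; the
    symmetric default averages both directions.  For N = 1 the denominator
    is the positive term alone, so the loss is exactly 0.
    """
    z_t = anp.atleast_2d(z_t)
    z_p = anp.atleast_2d(z_p)
    N = z_t.shape[0]
    if N == 0 or z_p.shape[0] != N:
        raise ValueError("batches must be non-empty and of equal size")
    if tau <= 0:
        raise ValueError("temperature must be positive")
    sims = (z_t @ z_p.T) / tau
    diag = anp.arange(N)

    def one_way(S):
        logz = anp.log(anp.sum(anp.exp(S - anp.max(S, axis=1, keepdims=True)),
                               axis=1)) + anp.max(S, axis=1)
        return anp.mean(logz - S[diag, diag])

    if direction == "t2p":
        return one_way(sims)
    if direction == "symmetric":
        return 0.5 * (one_way(sims) + one_way(sims.T))
    raise ValueError("direction must be 'symmetric' or 't2p'")


def alignment_metrics(z_t, z_p):
    """Positive-pair mean cosine, negative-pair mean, top-1 retrieval acc."""
    z_t, z_p = onp.atleast_2d(z_t), onp.atleast_2d(z_p)
    sims = z_t @ z_p.T
    N = sims.shape[0]
    pos = float(onp.mean(onp.diag(sims)))
    if N > 1:
        off = sims[~onp.eye(N, dtype=bool)]
        neg = float(onp.mean(off))
        acc = float(onp.mean(onp.argmax(sims, axis=1) == onp.arange(N)))
    else:
        neg, acc = float("nan"), 1.0
    return {"pos_sim": pos, "neg_sim": neg, "top1_acc": acc}


def _stage_loss(tree, Xb, Pb, t_cfg, c_cfg, tau, direction):
    h1 = encode_roi(tree["tst1"], Xb, t_cfg)
    h2 = encode_pcc(tree["tst2"], Pb, c_cfg)
    z_t = project(tree["head1"], h1)
    z_p = project(tree["head2"], h2)
    return infonce_loss(z_t, z_p, tau, direction)


def run_contrastive_stage(tst1_params, tst2_params, t_cfg: TemporalEncoderConfig,
                          c_cfg: ConnectivityEncoderConfig,
                          X_train, P_train, policy: FreezePolicy,
                          head_cfgs=None, epochs: int = 50, batch_size: int = 32,
                          lr: float = 1e-4, weight_decay: float = 1e-4,
                          tau: float = 0.07, direction: str = "symmetric",
                          seed: int = 0, X_val=None, P_val=None,
                          augment_window_len=None, verbose=False):
    """Train projection heads (and unfrozen encoders) with InfoNCE.

    Returns ``(tree, report)``: the updated parameter tree with keys
    ``tst1/tst2/head1/head2`` and a per-epoch alignment report containing
    the mean batch loss, the per-epoch mean *training* in-batch top-1
    retrieval accuracy (``train_top1``), and held-out alignment metrics
    (positive/negative mean cosine similarity and top-1 retrieval) computed
    on the validation arrays when provided, else on the training arrays.

    ``augment_window_len`` enables window augmentation: each view is
    computed from an independent random temporal window of the subject's
    series (the connectivity view's Pearson vector is recomputed on its
    window — the standard dynamic-FC construction).  Default off: positive
    pairs are the subject's full series and full-scan connectivity.
    """
    if batch_size < 2:
        raise ValueError("contrastive training needs batch_size >= 2 (no negatives)")
    rng = onp.random.default_rng(seed)
    if head_cfgs is None:
        head_cfgs = (ProjectionHeadConfig(t_cfg.d1), ProjectionHeadConfig(c_cfg.d2))
    tree = {
        "tst1": tree_copy(tst1_params),
        "tst2": tree_copy(tst2_params),
        "head1": init_projection_head(rng, head_cfgs[0]),
        "head2": init_projection_head(rng, head_cfgs[1]),
    }
    opt = Adam(tree, lr=lr, weight_decay=weight_decay,
               frozen=policy.frozen_modules())
    loss_grad = grad(lambda tr, Xb, Pb: _stage_loss(tr, Xb, Pb, t_cfg, c_cfg,
                                                    tau, direction))
    n = X_train.shape[0]
    T = X_train.shape[1]
    report = {"loss": [], "train_top1": [], "pos_sim": [], "neg_sim": [],
              "top1_acc": []}
    Xe = X_train if X_val is None else X_val
    Pe = P_train if P_val is None else P_val

    def batch_views(idx):
        if augment_window_len is None or augment_window_len >= T:
            return X_train[idx], P_train[idx]
        from .io import compute_pcc, flatten_upper
        w = augment_window_len
        s1 = rng.integers(0, T - w + 1, size=idx.size)
        s2 = rng.integers(0, T - w + 1, size=idx.size)
        Xb = onp.stack([X_train[i, a:a + w] for i, a in zip(idx, s1)])
        Pb = onp.stack([flatten_upper(compute_pcc(X_train[i, a:a + w])).values
                        for i, a in zip(idx, s2)])
        return Xb, Pb

    for epoch in range(epochs):
        order = rng.permutation(n)
        ep, ep_top1 = [], []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            if idx.size < 2:
                continue
            Xb, Pb = batch_views(idx)
            g = loss_grad(tree, Xb, Pb)
            ep.append(float(_stage_loss(tree, Xb, Pb, t_cfg, c_cfg, tau,
                                        direction)))
            tree = opt.step(tree, g)
            z_t = project(tree["head1"], encode_roi(tree["tst1"], Xb, t_cfg))
            z_p = project(tree["head2"], encode_pcc(tree["tst2"], Pb, c_cfg))
            ep_top1.append(alignment_metrics(z_t, z_p)["top1_acc"])
        z_t = project(tree["head1"], encode_roi(tree["tst1"], Xe, t_cfg))
        z_p = project(tree["head2"], encode_pcc(tree["tst2"], Pe, c_cfg))
        m = alignment_metrics(z_t, z_p)
        report["loss"].append(float(onp.mean(ep)) if ep else float("nan"))
        report["train_top1"].append(float(onp.mean(ep_top1)) if ep_top1 else float("nan"))
        for k in ("pos_sim", "neg_sim", "top1_acc"):
            report[k].append(m[k])
        if verbose:
            print(f"[contrastive] epoch {epoch + 1}: loss {report['loss'][-1]:.4f} "
                  f"pos {m['pos_sim']:.3f} neg {m['neg_sim']:.3f} "
                  f"top1 {m['top1_acc']:.3f}")
    return tree, report
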