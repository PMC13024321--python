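"""Supervised fine-tuning, evaluation metrics, LOSO protocol, and run
comparison statistics.

The full pipeline is pretrain -> contrastive alignment -> fine-tune.  This
module owns the fine-tuning stage (early stopping on validation AUC, best
checkpoint restored), the five evaluation metrics, leave-one-site-out
cross-validation with subject-level majority voting over sliding windows,
the relative-parameter-change diagnostic, and multi-seed comparisons with
paired t-tests under Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import autograd.numpy as anp
import numpy as onp
from autograd import grad
from scipy import stats
from sklearn.metrics import roc_auc_score

from ._nn import functional as F
from ._nn.optim import Adam, tree_copy
from .connectivity_encoder import ConnectivityEncoderConfig, encode_pcc
from .contrastive import FreezePolicy, project
from .fusion import FusionConfig, classifier_logits, fuse
from .temporal_encoder import TemporalEncoderConfig, encode_roi

__all__ = ["TrainConfig", "MetricsReport", "compute_metrics",
           "aggregate_metrics", "model_forward", "finetune", "evaluate",
           "loso_evaluate", "relative_parameter_change", "compare_runs",
           "make_windows"]


@dataclass
class TrainConfig:
    """Stage schedules and optimiser settings (full-scale defaults)."""

    pretrain_epochs: int = 100
    contrastive_epochs: int = 50
    finetune_epochs: int = 100
    early_stop_patience: int = 20
    lr_pretrain: float = 1e-4
    lr_contrastive: float = 1e-4
    lr_finetune: float = 5e-5
    weight_decay: float = 1e-4
    batch_size: int = 32
    finetune_freeze: FreezePolicy = field(default_factory=FreezePolicy)
    freeze_proj_heads: bool = False

    def __post_init__(self):
        if min(self.pretrain_epochs, self.contrastive_epochs,
               self.finetune_epochs) <= 0:
            raise ValueError("epochs must be positive")
        if self.early_stop_patience > self.finetune_epochs:
            raise ValueError("patience must be <= finetune epochs")


@dataclass
class MetricsReport:
    auc: float
    acc: float
    sensitivity: float
    specificity: float
    f1: float

    def as_dict(self):
        return {"auc": self.auc, "acc": self.acc,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity, "f1": self.f1}


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """AUC (rank-based), accuracy, sensitivity, specificity, F1 at threshold.

    ``scores`` are case-class probabilities.  AUC requires both classes.
    """
    y = onp.asarray(labels).astype(int)
    s = onp.asarray(scores, dtype=float)
    if len(onp.unique(y)) < 2:
        raise ValueError("AUC undefined: only one class present")
    auc = float(roc_auc_score(y, s))
    pred = (s >= threshold).astype(int)
    tp = int(onp.sum((pred == 1) & (y == 1)))
    tn = int(onp.sum((pred == 0) & (y == 0)))
    fp = int(onp.sum((pred == 1) & (y == 0)))
    fn = int(onp.sum((pred == 0) & (y == 1)))
    acc = (tp + tn) / y.size
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return MetricsReport(auc, float(acc), float(sens), float(spec), float(f1))


def aggregate_metrics(reports: Sequence[MetricsReport]) -> Dict[str, Tuple[float, float]]:
    """Per-metric (mean, sd) across seeds."""
    out = {}
    for k in ("auc", "acc", "sensitivity", "specificity", "f1"):
        vals = onp.array([getattr(r, k) for r in reports], dtype=float)
        out[k] = (float(vals.mean()), float(vals.std(ddof=1) if vals.size > 1 else 0.0))
    return out


# ---------------------------------------------------------------------------
# Fine-tuning
# ---------------------------------------------------------------------------

def model_forward(tree, X, P, t_cfg: TemporalEncoderConfig,
                  c_cfg: ConnectivityEncoderConfig, f_cfg: FusionConfig,
                  streams: str = "both", use_heads: bool = True,
                  clf_drops=None):
    """Logits of the full classifier for a batch of subjects.

    ``streams`` selects the dual model ("both") or a single-backbone
    ablation ("temporal" / "connectivity"); in single-backbone mode the same
    classifier head is applied directly to the lone (projected) feature.
    """
    feats = []
    if streams in ("both", "temporal"):
        h1 = encode_roi(tree["tst1"], X, t_cfg)
        if use_heads:
            h1 = project(tree["head1"], h1)
        feats.append(h1)
    if streams in ("both", "connectivity"):
        h2 = encode_pcc(tree["tst2"], P, c_cfg)
        if use_heads:
            h2 = project(tree["head2"], h2)
        feats.append(h2)
    if streams == "both":
        fused = fuse(tree["fusion"], feats[0], feats[1], f_cfg)
    else:
        fused = feats[0]
    return classifier_logits(tree["clf"], fused, clf_drops)


def _ce_loss(tree, X, P, y, t_cfg, c_cfg, f_cfg, streams, use_heads, clf_drops):
    logits = model_forward(tree, X, P, t_cfg, c_cfg, f_cfg, streams,
                           use_heads, clf_drops)
    logp = F.log_softmax(logits, axis=-1)
    idx = onp.arange(y.size)
    return -anp.mean(logp[idx, onp.asarray(y)])


def predict_proba_tree(tree, X, P, t_cfg, c_cfg, f_cfg, streams="both",
                       use_heads=True):
    logits = model_forward(tree, X, P, t_cfg, c_cfg, f_cfg, streams, use_heads)
    return onp.asarray(F.softmax(logits, axis=-1))


def finetune(tree, t_cfg, c_cfg, f_cfg, X_tr, P_tr, y_tr, X_val, P_val, y_val,
             cfg: TrainConfig, streams: str = "both", use_heads: bool = True,
             seed: int = 0, verbose: bool = False):
    """Supervised stage: cross-entropy descent with early stopping on
    validation AUC (patience ``cfg.early_stop_patience``); the parameters at
    the best validation AUC are restored before returning.

    Returns ``(best_tree, history)`` with per-epoch train loss and val AUC.
    """
    if y_val is None or len(y_val) == 0:
        raise ValueError("fine-tuning requires a non-empty validation split")
    rng = onp.random.default_rng(seed)
    tree = {k: tree_copy(v) for k, v in tree.items()}
    frozen = set(cfg.finetune_freeze.frozen_modules())
    if cfg.freeze_proj_heads:
        frozen |= {"head1", "head2"}
    frozen &= set(tree.keys())
    opt = Adam(tree, lr=cfg.lr_finetune, weight_decay=cfg.weight_decay,
               frozen=frozen)
    loss_grad = grad(lambda tr, Xb, Pb, yb, d: _ce_loss(
        tr, Xb, Pb, yb, t_cfg, c_cfg, f_cfg, streams, use_heads, d))
    n = len(y_tr)
    best_auc, best_tree, best_epoch = -onp.inf, {k: tree_copy(v) for k, v in tree.items()}, 0
    history = {"train_loss": [], "val_auc": []}
    for epoch in range(cfg.finetune_epochs):
        order = rng.permutation(n)
        ep = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            drops = None
            if f_cfg.dropout > 0:
                drops = [F.dropout_mask(rng, (idx.size, h), f_cfg.dropout)
                         for h in f_cfg.classifier_hidden[:-1]]
            g = loss_grad(tree, X_tr[idx], P_tr[idx], y_tr[idx], drops)
            ep.append(float(_ce_loss(tree, X_tr[idx], P_tr[idx], y_tr[idx],
                                     t_cfg, c_cfg, f_cfg, streams, use_heads, drops)))
            tree = opt.step(tree, g)
        proba = predict_proba_tree(tree, X_val, P_val, t_cfg, c_cfg, f_cfg,
                                   streams, use_heads)
        val_auc = compute_metrics(y_val, proba[:, 1]).auc
        history["train_loss"].append(float(onp.mean(ep)))
        history["val_auc"].append(val_auc)
        # ties resolve to the later checkpoint: with small validation sets
        # the AUC saturates quickly and continued optimisation at equal
        # validation evidence is preferable to an early frozen snapshot
        if val_auc >= best_auc:
            best_auc, best_epoch = val_auc, epoch
            best_tree = {k: tree_copy(v) for k, v in tree.items()}
        if verbose:
            print(f"[finetune] epoch {epoch + 1}: loss {history['train_loss'][-1]:.4f} "
                  f"val AUC {val_auc:.3f}")
        if epoch - best_epoch >= cfg.early_stop_patience:
            break
    return best_tree, history


def evaluate(tree, t_cfg, c_cfg, f_cfg, X, P, y, streams="both",
             use_heads=True, threshold: float = 0.5) -> MetricsReport:
    proba = predict_proba_tree(tree, X, P, t_cfg, c_cfg, f_cfg, streams, use_heads)
    return compute_metrics(y, proba[:, 1], threshold)


# ---------------------------------------------------------------------------
# Leave-one-site-out with sliding-window majority voting
# ---------------------------------------------------------------------------

def make_windows(T: int, window_len: Optional[int], window_stride: Optional[int]):
    """(start, stop) pairs; default is one full-length window."""
    if window_len is None or window_len >= T:
        return [(0, T)]
    stride = window_stride or window_len
    starts = list(range(0, T - window_len + 1, stride))
    return [(s, s + window_len) for s in starts]


def majority_vote(window_preds: Sequence[int]) -> int:
    """Subject-level call from window-level class predictions; ties are
    broken toward the positive class (sensitivity-preserving)."""
    votes = onp.asarray(window_preds)
    pos = int(onp.sum(votes == 1))
    neg = votes.size - pos
    return 1 if pos >= neg else 0


def subject_level_predictions(estimator, X_test, window_len=None,
                              window_stride=None, threshold: float = 0.5):
    """Window the series, predict per window, aggregate per subject.

    Returns ``(pred, score)``: majority-vote class and mean window
    case-probability (the continuous score used for AUC).  With a single
    full-length window this reduces bit-exactly to plain evaluation.
    """
    T = X_test.shape[1]
    windows = make_windows(T, window_len, window_stride)
    probs = onp.stack([estimator.predict_proba(X_test[:, a:b, :])[:, 1]
                       for (a, b) in windows], axis=1)   # (n, n_windows)
    preds = (probs >= threshold).astype(int)
    vote = onp.array([majority_vote(row) for row in preds])
    score = probs.mean(axis=1)
    return vote, score


def loso_evaluate(make_estimator: Callable[[], object], X, y, sites,
                  window_len=None, window_stride=None, threshold: float = 0.5,
                  verbose: bool = False):
    """Leave-one-site-out cross-validation.

    For each site, an estimator built by ``make_estimator()`` is fitted on
    all other sites and evaluated on the held-out site with subject-level
    majority voting across sliding windows.  Sites whose held-out subjects
    contain a single class get ``auc = nan`` (undefined) but keep the
    thresholded metrics.  Returns a list of per-site dicts.
    """
    y = onp.asarray(y)
    sites = onp.asarray(sites)
    uniq = list(dict.fromkeys(sites.tolist()))
    if len(uniq) < 2:
        raise ValueError("LOSO needs at least 2 sites")
    rows = []
    for site in uniq:
        test_idx = onp.flatnonzero(sites == site)
        train_idx = onp.flatnonzero(sites != site)
        if test_idx.size < 1:
            continue
        est = make_estimator()
        est.fit(X[train_idx], y[train_idx])
        pred, score = subject_level_predictions(est, X[test_idx], window_len,
                                                window_stride, threshold)
        y_t = y[test_idx]
        row = {"site": site, "n_test": int(test_idx.size),
               "train_idx": train_idx, "test_idx": test_idx}
        if len(onp.unique(y_t)) < 2:
            row["auc"] = float("nan")
        else:
            row["auc"] = float(roc_auc_score(y_t, score))
        tp = int(onp.sum((pred == 1) & (y_t == 1)))
        tn = int(onp.sum((pred == 0) & (y_t == 0)))
        fp = int(onp.sum((pred == 1) & (y_t == 0)))
        fn = int(onp.sum((pred == 0) & (y_t == 1)))
        row["acc"] = (tp + tn) / y_t.size
        row["sensitivity"] = tp / (tp + fn) if tp + fn else float("nan")
        row["specificity"] = tn / (tn + fp) if tn + fp else float("nan")
        row["f1"] = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        rows.append(row)
        if verbose:
            print(f"[loso] site {site}: AUC {row['auc']:.3f} ACC {row['acc']:.3f}")
    return rows


# ---------------------------------------------------------------------------
# Diagnostics and multi-seed statistics
# ---------------------------------------------------------------------------

def _leaves(tree):
    if isinstance(tree, dict):
        for k in sorted(tree):
            yield from _leaves(tree[k])
    elif isinstance(tree, (list, tuple)):
        for v in tree:
            yield from _leaves(v)
    else:
        yield onp.asarray(tree)


def relative_parameter_change(theta_before, theta_after) -> float:
    """Mean over parameter tensors of ||after - before||_F / ||before||_F.

    Tensors whose reference norm is zero (e.g. zero-initialised biases)
    carry no scale information and are excluded from the average, so an
    untouched module gives exactly 0 and doubling every tensor gives
    exactly 1.
    """
    before = list(_leaves(theta_before))
    after = list(_leaves(theta_after))
    if len(before) != len(after) or any(b.shape != a.shape
                                        for b, a in zip(before, after)):
        raise ValueError("parameter structures do not match")
    ratios = [onp.linalg.norm(a - b) / onp.linalg.norm(b)
              for b, a in zip(before, after) if onp.linalg.norm(b) > 0]
    return float(onp.mean(ratios)) if ratios else 0.0


def compare_runs(metric_vectors: Dict[str, Sequence[float]],
                 comparisons: Optional[List[Tuple[str, str]]] = None,
                 alpha_levels=(0.05, 0.01, 0.001)):
    """Paired two-tailed t-tests between configurations' per-seed metrics,
    Bonferroni-corrected over the number of comparisons.

    Degenerate cases: identical vectors report p = 1 ("no difference"); a
    constant nonzero difference (sd of differences = 0) is flagged and
    reported as p = 0.
    """
    names = list(metric_vectors)
    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    n_comp = len(comparisons)
    rows = []
    for a, b in comparisons:
        va = onp.asarray(metric_vectors[a], dtype=float)
        vb = onp.asarray(metric_vectors[b], dtype=float)
        if va.size != vb.size:
            raise ValueError("compared configs must have equal seed counts")
        if va.size < 2:
            raise ValueError("need at least 2 seeds for a paired t-test")
        diff = va - vb
        flag = ""
        if onp.allclose(diff, 0):
            t, p = 0.0, 1.0
            flag = "no difference"
        elif onp.std(diff, ddof=1) == 0:
            t, p = onp.inf * onp.sign(diff.mean()), 0.0
            flag = "degenerate sd (constant difference)"
        else:
            t, p = stats.ttest_rel(va, vb)
        p_adj = min(1.0, float(p) * n_comp)
        stars = "".join("*" for lvl in alpha_levels if p_adj < lvl)
        rows.append({"a": a, "b": b, "mean_diff": float(diff.mean()),
                     "t": float(t), "p": float(p), "p_adj": p_adj,
                     "stars": stars, "flag": flag})
    return rows
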