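"""scikit-learn style estimators.

:class:`DualStreamClassifier` is the package's front door: ``fit`` runs the
three-stage pipeline (masked-reconstruction pre-training of both stream
encoders, InfoNCE contrastive alignment of their projection heads, then
supervised fine-tuning with one of five fusion operators) on an array of
per-subject ROI time-series matrices, and ``predict_proba`` scores new
subjects.  Connectivity vectors are derived internally with the package's
Pearson/upper-triangle convention, so the input contract is simply
``X`` of shape ``(n_subjects, T, R)`` and binary ``y``.

:class:`PearsonConnectivity` is a small transformer turning series into
flattened connectivity vectors for use in ordinary sklearn pipelines.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from ._nn.optim import tree_copy
from .connectivity_encoder import (ConnectivityEncoderConfig,
                                   init_connectivity_encoder,
                                   pretrain_connectivity)
from .contrastive import (FreezePolicy, ProjectionHeadConfig,
                          run_contrastive_stage)
from .fusion import FusionConfig, fused_dim, init_classifier, init_fusion
from .io import compute_pcc, flatten_upper
from .simulate import stratified_split_indices
from .temporal_encoder import (TemporalEncoderConfig, init_temporal_encoder,
                               pretrain_temporal)
from .train import TrainConfig, finetune, predict_proba_tree

__all__ = ["DualStreamClassifier", "PearsonConnectivity"]


class PearsonConnectivity(TransformerMixin, BaseEstimator):
    """Transform (n, T, R) series into (n, D) flattened Pearson vectors."""

    def fit(self, X, y=None):
        X = np.asarray(X)
        self.n_rois_ = X.shape[2]
        return self

    def transform(self, X):
        X = np.asarray(X)
        return np.stack([flatten_upper(compute_pcc(x)).values for x in X])


def _pcc_matrix(X):
    return np.stack([flatten_upper(compute_pcc(x)).values for x in X])


class DualStreamClassifier(ClassifierMixin, BaseEstimator):
    """Dual-stream Transformer classifier over ROI time series.

    Parameters follow sklearn conventions (all settable via ``set_params``);
    dimensions default to a desk-scale configuration suitable for a few
    hundred subjects and a few dozen ROIs — for the full-scale architecture
    pass d1=512, L1=6, d2=256, L2=2, ff1=2048, ff2=512, patch_len=100.

    Parameters
    ----------
    fusion : one of {"concat", "gated", "cross_attention", "bilinear",
        "attention_pooling"}.
    streams : "both" (dual-stream), or the single-backbone ablations
        "temporal" / "connectivity".
    use_pretraining, use_contrastive : stage toggles for ablation studies;
        disabling contrastive also removes the projection heads from the
        fine-tuned model.
    contrastive_freeze, finetune_freeze : freeze-policy names
        ("both"/"tst1"/"tst2"/"none") for the encoders in each stage.
    val_fraction : share of the training data held out (stratified) for
        early stopping on validation AUC.

    Attributes
    ----------
    params_ : fitted parameter tree (tst1/tst2/head1/head2/fusion/clf).
    history_ : per-stage training curves.
    classes_ : the two class labels.
    """

    def __init__(self, d1=32, L1=1, heads1=4, ff1=64,
                 d2=32, L2=1, heads2=4, ff2=64, patch_len=10,
                 proj_hidden=64, proj_out=32, d_f=32,
                 classifier_hidden=(64, 32, 2),
                 fusion="attention_pooling", streams="both",
                 dropout=0.1, classifier_dropout=0.3,
                 mask_ratio_range=(0.25, 0.5), m2=0.15,
                 pretrain_epochs=15, contrastive_epochs=10,
                 finetune_epochs=40, early_stop_patience=10,
                 lr_pretrain=1e-3, lr_contrastive=1e-3, lr_finetune=1e-3,
                 weight_decay=1e-4, batch_size=32,
                 use_pretraining=True, use_contrastive=True,
                 contrastive_freeze="none", finetune_freeze="none",
                 freeze_proj_heads=False, temperature=0.07,
                 infonce_direction="symmetric", val_fraction=0.15,
                 random_state=0, verbose=False):
        self.d1 = d1
        self.L1 = L1
        self.heads1 = heads1
        self.ff1 = ff1
        self.d2 = d2
        self.L2 = L2
        self.heads2 = heads2
        self.ff2 = ff2
        self.patch_len = patch_len
        self.proj_hidden = proj_hidden
        self.proj_out = proj_out
        self.d_f = d_f
        self.classifier_hidden = classifier_hidden
        self.fusion = fusion
        self.streams = streams
        self.dropout = dropout
        self.classifier_dropout = classifier_dropout
        self.mask_ratio_range = mask_ratio_range
        self.m2 = m2
        self.pretrain_epochs = pretrain_epochs
        self.contrastive_epochs = contrastive_epochs
        self.finetune_epochs = finetune_epochs
        self.early_stop_patience = early_stop_patience
        self.lr_pretrain = lr_pretrain
        self.lr_contrastive = lr_contrastive
        self.lr_finetune = lr_finetune
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.use_pretraining = use_pretraining
        self.use_contrastive = use_contrastive
        self.contrastive_freeze = contrastive_freeze
        self.finetune_freeze = finetune_freeze
        self.freeze_proj_heads = freeze_proj_heads
        self.temperature = temperature
        self.infonce_direction = infonce_direction
        self.val_fraction = val_fraction
        self.random_state = random_state
        self.verbose = verbose

    # -- configuration assembly ------------------------------------------

    def _configs(self, T, R):
        D = R * (R - 1) // 2
        t_cfg = TemporalEncoderConfig(
            n_rois=R, d1=self.d1, L1=self.L1, heads=self.heads1,
            ff_dim=self.ff1, dropout=self.dropout,
            mask_ratio_range=tuple(self.mask_ratio_range))
        c_cfg = ConnectivityEncoderConfig(
            D=D, d2=self.d2, L2=self.L2, heads=self.heads2,
            ff_dim=self.ff2, dropout=self.dropout,
            patch_len=min(self.patch_len, D), m2=self.m2)
        f_cfg = FusionConfig(
            method=self.fusion, d_f=self.d_f,
            classifier_hidden=list(self.classifier_hidden),
            dropout=self.classifier_dropout)
        return t_cfg, c_cfg, f_cfg

    def _validate_input(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_subjects, T, R)")
        if y is not None:
            y = np.asarray(y)
            if y.shape[0] != X.shape[0]:
                raise ValueError("X and y length mismatch")
        return X, y

    # -- pipeline --------------------------------------------------------

    def fit(self, X, y, init_encoders=None):
        """Run the pipeline.  ``init_encoders`` optionally warm-starts the
        encoders with externally pre-trained parameter trees (keys ``tst1``/
        ``tst2``), in which case the pre-training stage is skipped for the
        provided modules — used e.g. to share one pre-training run across
        ablation arms."""
        X, y = self._validate_input(X, y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("binary classification requires exactly 2 classes")
        self.classes_ = classes
        y01 = (y == classes[1]).astype(int)
        n, T, R = X.shape
        self.n_time_points_, self.n_rois_ = T, R
        t_cfg, c_cfg, f_cfg = self._configs(T, R)
        self.t_cfg_, self.c_cfg_, self.f_cfg_ = t_cfg, c_cfg, f_cfg
        rng = np.random.default_rng(self.random_state)
        P = _pcc_matrix(X)
        self.history_ = {}

        tr_idx, val_idx = stratified_split_indices(
            y01, (1 - self.val_fraction, self.val_fraction),
            seed=int(rng.integers(2 ** 31)))
        X_tr, X_val = X[tr_idx], X[val_idx]
        P_tr, P_val = P[tr_idx], P[val_idx]
        y_tr, y_val = y01[tr_idx], y01[val_idx]

        use_t = self.streams in ("both", "temporal")
        use_c = self.streams in ("both", "connectivity")

        init_encoders = init_encoders or {}
        tst1 = (tree_copy(init_encoders["tst1"]) if "tst1" in init_encoders
                else init_temporal_encoder(rng, t_cfg))
        tst2 = (tree_copy(init_encoders["tst2"]) if "tst2" in init_encoders
                else init_connectivity_encoder(rng, c_cfg))

        if self.use_pretraining:
            if use_t and "tst1" not in init_encoders:
                tst1, h = pretrain_temporal(
                    tst1, X_tr, X_val, t_cfg, epochs=self.pretrain_epochs,
                    batch_size=self.batch_size, lr=self.lr_pretrain,
                    weight_decay=self.weight_decay,
                    seed=int(rng.integers(2 ** 31)), verbose=self.verbose)
                self.history_["pretrain_temporal"] = h
            if use_c and "tst2" not in init_encoders:
                tst2, h = pretrain_connectivity(
                    tst2, P_tr, P_val, c_cfg, epochs=self.pretrain_epochs,
                    batch_size=self.batch_size, lr=self.lr_pretrain,
                    weight_decay=self.weight_decay,
                    seed=int(rng.integers(2 ** 31)), verbose=self.verbose)
                self.history_["pretrain_connectivity"] = h

        head_cfgs = (ProjectionHeadConfig(t_cfg.d1, self.proj_hidden, self.proj_out),
                     ProjectionHeadConfig(c_cfg.d2, self.proj_hidden, self.proj_out))
        if self.use_contrastive:
            tree, report = run_contrastive_stage(
                tst1, tst2, t_cfg, c_cfg, X_tr, P_tr,
                FreezePolicy.from_name(self.contrastive_freeze),
                head_cfgs=head_cfgs, epochs=self.contrastive_epochs,
                batch_size=self.batch_size, lr=self.lr_contrastive,
                weight_decay=self.weight_decay, tau=self.temperature,
                direction=self.infonce_direction,
                seed=int(rng.integers(2 ** 31)),
                X_val=X_val, P_val=P_val, verbose=self.verbose)
            self.history_["contrastive"] = report
        else:
            tree = {"tst1": tst1, "tst2": tst2}

        self.use_heads_ = self.use_contrastive
        feat_dim_t = self.proj_out if self.use_heads_ else t_cfg.d1
        feat_dim_c = self.proj_out if self.use_heads_ else c_cfg.d2
        ft_tree = {}
        if use_t:
            ft_tree["tst1"] = tree["tst1"]
            if self.use_heads_:
                ft_tree["head1"] = tree["head1"]
        if use_c:
            ft_tree["tst2"] = tree["tst2"]
            if self.use_heads_:
                ft_tree["head2"] = tree["head2"]
        if self.streams == "both":
            ft_tree["fusion"] = init_fusion(rng, feat_dim_t, feat_dim_c, f_cfg)
            clf_in = fused_dim(f_cfg)
        else:
            clf_in = feat_dim_t if self.streams == "temporal" else feat_dim_c
        ft_tree["clf"] = init_classifier(rng, clf_in, f_cfg)

        train_cfg = TrainConfig(
            pretrain_epochs=max(1, self.pretrain_epochs),
            contrastive_epochs=max(1, self.contrastive_epochs),
            finetune_epochs=self.finetune_epochs,
            early_stop_patience=min(self.early_stop_patience, self.finetune_epochs),
            lr_pretrain=self.lr_pretrain, lr_contrastive=self.lr_contrastive,
            lr_finetune=self.lr_finetune, weight_decay=self.weight_decay,
            batch_size=self.batch_size,
            finetune_freeze=FreezePolicy.from_name(self.finetune_freeze),
            freeze_proj_heads=self.freeze_proj_heads)
        self.pretrained_tree_ = {k: tree_copy(v) for k, v in ft_tree.items()}
        best, hist = finetune(
            ft_tree, t_cfg, c_cfg, f_cfg, X_tr, P_tr, y_tr, X_val, P_val, y_val,
            train_cfg, streams=self.streams, use_heads=self.use_heads_,
            seed=int(rng.integers(2 ** 31)), verbose=self.verbose)
        self.params_ = best
        self.history_["finetune"] = hist
        return self

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def predict_proba(self, X):
        self._check_fitted()
        X, _ = self._validate_input(X)
        P = _pcc_matrix(X)
        return predict_proba_tree(self.params_, X, P, self.t_cfg_, self.c_cfg_,
                                  self.f_cfg_, self.streams, self.use_heads_)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[(proba[:, 1] >= 0.5).astype(int)]

    def decision_function(self, X):
        proba = self.predict_proba(X)
        return proba[:, 1]
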