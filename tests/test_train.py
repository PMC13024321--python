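"""Metrics, fine-tuning contracts, LOSO protocol, run comparison."""

import numpy as np
import pytest
from scipy import stats

from connfusion._nn.optim import tree_hash
from connfusion.contrastive import FreezePolicy
from connfusion.estimator import DualStreamClassifier
from connfusion.train import (TrainConfig, compare_runs, compute_metrics,
                              loso_evaluate, majority_vote, make_windows,
                              relative_parameter_change,
                              subject_level_predictions)


class TestComputeMetrics:
    def test_perfect_separation(self):
        m = compute_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert m.auc == 1.0 and m.acc == 1.0 and m.f1 == 1.0

    def test_constant_scores_auc_half(self):
        m = compute_metrics([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert m.auc == pytest.approx(0.5)

    def test_pairwise_enumeration_oracle(self):
        # labels (1,1,0,0), scores (0.9, 0.4, 0.6, 0.1):
        # positive-negative pairs won: (0.9>0.6), (0.9>0.1), (0.4<0.6 lost),
        # (0.4>0.1) -> 3/4
        y = [1, 1, 0, 0]
        s = [0.9, 0.4, 0.6, 0.1]
        m = compute_metrics(y, s)
        assert m.auc == pytest.approx(3 / 4)
        # thresholded at 0.5: preds (1, 0, 1, 0) -> tp=1 fn=1 fp=1 tn=1
        assert m.acc == pytest.approx(0.5)
        assert m.sensitivity == pytest.approx(0.5)
        assert m.specificity == pytest.approx(0.5)
        assert m.f1 == pytest.approx(2 * 1 / (2 * 1 + 1 + 1))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([1, 1, 1], [0.1, 0.5, 0.9])


class TestRelativeParameterChange:
    def test_unchanged_gives_zero(self):
        tree = {"a": np.ones((3, 3)), "b": [np.arange(4.0)]}
        assert relative_parameter_change(tree, tree) == 0.0

    def test_doubling_gives_one(self):
        before = {"a": np.random.default_rng(0).standard_normal((3, 3)),
                  "b": [np.arange(1.0, 5.0)]}
        after = {"a": before["a"] * 2, "b": [before["b"][0] * 2]}
        assert relative_parameter_change(before, after) == pytest.approx(1.0)

    def test_hand_computed_two_tensor_module(self):
        b1 = np.array([[3.0, 4.0]])          # ||.||_F = 5
        b2 = np.array([1.0, 2.0, 2.0])       # ||.||_F = 3
        a1 = np.array([[6.0, 8.0]])          # delta norm 5 -> ratio 1
        a2 = np.array([1.0, 2.0, 5.0])       # delta (0,0,3) -> ratio 1
        want = 0.5 * (5 / 5 + 3 / 3)
        got = relative_parameter_change({"m": [b1, b2]}, {"m": [a1, a2]})
        assert got == pytest.approx(want, rel=1e-9)

    def test_structure_mismatch_rejected(self):
        with pytest.raises(ValueError):
            relative_parameter_change({"a": np.ones(3)}, {"a": np.ones(4)})


class TestCompareRuns:
    def test_identical_vectors_no_difference(self):
        rows = compare_runs({"a": [0.7, 0.7, 0.7], "b": [0.7, 0.7, 0.7]})
        assert rows[0]["p_adj"] == 1.0
        assert rows[0]["flag"] == "no difference"

    def test_constant_difference_flagged_degenerate(self):
        a = [0.70, 0.71, 0.72, 0.73, 0.74]
        b = [0.60, 0.61, 0.62, 0.63, 0.64]
        rows = compare_runs({"a": a, "b": b})
        assert rows[0]["mean_diff"] == pytest.approx(0.10)
        assert "degenerate" in rows[0]["flag"]
        assert rows[0]["p_adj"] == 0.0

    def test_matches_scipy_paired_t(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.7, 0.02, 5)
        b = rng.normal(0.6, 0.02, 5)
        rows = compare_runs({"a": a, "b": b})
        t, p = stats.ttest_rel(a, b)
        assert rows[0]["t"] == pytest.approx(t)
        assert rows[0]["p"] == pytest.approx(p)

    def test_bonferroni_multiplies_by_comparison_count(self):
        rng = np.random.default_rng(2)
        vecs = {k: rng.normal(0.7, 0.05, 4) for k in "abcde"}
        rows = compare_runs(vecs)          # 10 pairwise comparisons
        assert len(rows) == 10
        for r in rows:
            assert r["p_adj"] == pytest.approx(min(1.0, r["p"] * 10))

    def test_unequal_or_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            compare_runs({"a": [0.7, 0.8], "b": [0.7]})
        with pytest.raises(ValueError):
            compare_runs({"a": [0.7], "b": [0.6]})


class TestWindowsAndVoting:
    def test_default_single_full_window(self):
        assert make_windows(100, None, None) == [(0, 100)]
        assert make_windows(100, 150, 10) == [(0, 100)]

    def test_window_grid(self):
        assert make_windows(10, 4, 3) == [(0, 4), (3, 7), (6, 10)]

    def test_majority_vote_and_positive_tie_break(self):
        assert majority_vote([1, 1, 0]) == 1
        assert majority_vote([0, 0, 1]) == 0
        assert majority_vote([1, 0]) == 1      # tie -> positive class


def _fast_estimator(**kw):
    base = dict(use_pretraining=False, use_contrastive=False,
                pretrain_epochs=2, contrastive_epochs=2, finetune_epochs=8,
                early_stop_patience=8, d1=16, L1=1, heads1=2, ff1=32,
                d2=16, L2=1, heads2=2, ff2=32, patch_len=10, d_f=16,
                proj_hidden=16, proj_out=8, classifier_hidden=(16, 8, 2),
                random_state=0)
    base.update(kw)
    return DualStreamClassifier(**base)


class TestFinetuneContracts:
    def test_freeze_policy_and_determinism(self, tiny_dataset):
        X, y = tiny_dataset["X"], tiny_dataset["y"]
        est = _fast_estimator(use_contrastive=True,
                              finetune_freeze="both", freeze_proj_heads=True)
        est.fit(X, y)
        pre = est.pretrained_tree_
        post = est.params_
        for frozen_key in ("tst1", "tst2", "head1", "head2"):
            assert tree_hash(pre[frozen_key]) == tree_hash(post[frozen_key])
            assert relative_parameter_change(pre[frozen_key],
                                             post[frozen_key]) == 0.0
        assert tree_hash(pre["clf"]) != tree_hash(post["clf"])

        est2 = _fast_estimator(use_contrastive=True,
                               finetune_freeze="both", freeze_proj_heads=True)
        est2.fit(X, y)
        assert np.array_equal(est.predict_proba(X), est2.predict_proba(X))

    def test_early_stopping_never_exceeds_patience_past_best(self, tiny_dataset):
        X, y = tiny_dataset["X"], tiny_dataset["y"]
        est = _fast_estimator(finetune_epochs=30, early_stop_patience=3)
        est.fit(X, y)
        aucs = est.history_["finetune"]["val_auc"]
        # best-epoch ties resolve to the latest occurrence
        best = len(aucs) - 1 - int(np.argmax(aucs[::-1]))
        assert len(aucs) <= best + 3 + 1


class TestLoso:
    def test_partitions_disjoint_and_votes(self, tiny_dataset):
        X, y, sites = (tiny_dataset["X"], tiny_dataset["y"],
                       tiny_dataset["sites"])
        rows = loso_evaluate(_fast_estimator, X, y, sites)
        assert len(rows) == 3
        for r in rows:
            assert set(r["train_idx"]).isdisjoint(set(r["test_idx"]))
            assert set(r["train_idx"]) | set(r["test_idx"]) == set(range(len(y)))
            assert np.isfinite(r["acc"])

    def test_single_window_equals_plain_evaluation(self, tiny_dataset):
        X, y = tiny_dataset["X"], tiny_dataset["y"]
        est = _fast_estimator()
        est.fit(X[:40], y[:40])
        pred, score = subject_level_predictions(est, X[40:])
        plain = est.predict_proba(X[40:])[:, 1]
        assert np.array_equal(score, plain)
        assert np.array_equal(pred, (plain >= 0.5).astype(int))

    def test_single_site_rejected(self, tiny_dataset):
        X, y = tiny_dataset["X"], tiny_dataset["y"]
        with pytest.raises(ValueError):
            loso_evaluate(_fast_estimator, X, y, ["s"] * len(y))
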