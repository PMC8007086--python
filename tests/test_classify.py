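"""Fold construction, SVM evaluation, and AUC against pair-counting oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phonation import (
    ExperimentConfig,
    make_folds,
    roc_auc,
    run_experiment,
    run_seven_configurations,
    summary_table,
    train_eval_svm,
)
from phonation.synth import synthesize_null_features


def auc_pair_counting(scores, labels):
    """Brute-force all-pairs concordance (ties count half)."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def shifted_null(n_co, n_pd, shift_cols, shift, seed):
    features, labels = synthesize_null_features(n_co, n_pd, seed=seed)
    for group, delta in shift.items():
        mask = features.index.get_level_values("group") == group
        features.loc[mask, shift_cols] += delta
    return features, labels


class TestRocAuc:
    def test_perfect_scores(self):
        roc, auc = roc_auc([0.0, 0.0, 1.0, 1.0], [0, 0, 1, 1])
        assert auc == 1.0
        assert roc.iloc[0]["tpr"] == 0.0 and roc.iloc[-1]["tpr"] == 1.0
        assert roc.iloc[0]["fpr"] == 0.0 and roc.iloc[-1]["fpr"] == 1.0

    def test_constant_scores_chance(self):
        _, auc = roc_auc(np.ones(10), [0, 1] * 5)
        assert auc == 0.5

    def test_hand_counted_example(self):
        _, auc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75, rel=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @given(seed=st.integers(0, 10_000), n=st.integers(4, 200),
           with_ties=st.booleans())
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_matches_pair_counting_oracle(self, seed, n, with_ties):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = rng.standard_normal(n)
        if with_ties:
            scores = np.round(scores, 1)
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(auc_pair_counting(scores, labels), rel=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        scores = rng.standard_normal(50)
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(np.exp(3.0 * scores) + 7.0, labels)
        assert a1 == pytest.approx(a2, rel=1e-12)


class TestFolds:
    def test_five_equal_test_folds_for_full_cohort(self):
        y = np.array([0] * 220 + [1] * 240)
        folds = make_folds(y, n_folds=5, seed=0)
        sizes = sorted(len(test) for _, test in folds)
        assert sizes == [92] * 5
        covered = np.sort(np.concatenate([test for _, test in folds]))
        np.testing.assert_array_equal(covered, np.arange(460))

    def test_stratification(self):
        y = np.array([0] * 220 + [1] * 240)
        for _, test in make_folds(y, n_folds=5, seed=0):
            assert np.sum(y[test] == 0) == 44 and np.sum(y[test] == 1) == 48

    def test_subject_granularity_keeps_subjects_whole(self):
        y = np.repeat(np.r_[np.zeros(22), np.ones(24)].astype(int), 10)
        subjects = np.repeat(np.arange(46), 10)
        folds = make_folds(y, groups=subjects, n_folds=5, granularity="subject", seed=0)
        for train, test in folds:
            assert not set(subjects[train]) & set(subjects[test])

    def test_same_seed_identical_folds(self):
        y = np.array([0, 1] * 30)
        f1 = make_folds(y, n_folds=5, seed=3)
        f2 = make_folds(y, n_folds=5, seed=3)
        for (a, b), (c, d) in zip(f1, f2):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)

    def test_class_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.array([0] * 5 + [1] * 50), n_folds=5)


class TestTrainEvalSvm:
    def test_separable_blobs_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-5, 0.3, (40, 4)), rng.normal(5, 0.3, (40, 4))])
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        scores, labels = train_eval_svm(X, y, X)
        assert np.array_equal(labels, y)

    def test_single_class_train_fold_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ValueError):
            train_eval_svm(X, np.zeros(10, int), X)

    def test_duplicated_training_rows_equal_doubled_c(self):
        """Doubling every training row is exactly a doubling of the slack
        penalty C: the decision function must match on a tiny instance."""
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(-1, 1, (15, 2)), rng.normal(1, 1, (15, 2))])
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        Xt = rng.standard_normal((8, 2))
        s1, _ = train_eval_svm(X, y, Xt, ExperimentConfig(gamma=0.5, C=2.0, tol=1e-9))
        s2, _ = train_eval_svm(np.vstack([X, X]), np.r_[y, y], Xt,
                               ExperimentConfig(gamma=0.5, C=1.0, tol=1e-9))
        assert np.max(np.abs(s1 - s2)) < 1e-6


class TestExperiments:
    def test_effect_in_one_phoneme_ranks_that_phoneme_first(self):
        features, labels = shifted_null(
            12, 12, [f"m_{f}" for f in ("jit_abs", "jit_rel", "shim_db", "hnr")],
            {"PD-off": 1.5}, seed=2,
        )
        reports = run_seven_configurations(features, labels, "pdon-vs-pdoff", seed=2)
        assert reports["m"].auc > reports["a"].auc
        assert reports["m"].auc > reports["o"].auc

    def test_pooling_phonemes_does_not_hurt(self):
        cols = [f"{ph}_{f}" for ph in "aom" for f in ("jit_abs", "shim_db", "hnr")]
        features, labels = shifted_null(12, 12, cols, {"PD-off": 1.0}, seed=3)
        reports = run_seven_configurations(features, labels, "co-vs-pdoff", seed=3)
        best_single = max(reports[ph].auc for ph in ("a", "o", "m"))
        assert reports["a+o+m"].auc >= best_single - 0.02

    def test_confusion_counts_sum_to_dataset_size(self):
        features, labels = shifted_null(8, 8, ["a_jit_abs"], {"PD-off": 1.0}, seed=4)
        rep = run_experiment(features, labels,
                             ExperimentConfig(feature_subset="a+o+m",
                                              comparison="co-vs-pdoff", seed=4))
        n_rows = int((labels.isin(["CO", "PD-off"])).sum())
        assert rep.tp + rep.tn + rep.fp + rep.fn == n_rows
        assert 0.0 <= rep.auc <= 1.0
        assert rep.per_fold["n_test"].sum() == n_rows

    def test_seed_reproducibility(self):
        features, labels = shifted_null(8, 8, ["a_jit_abs"], {"PD-off": 1.0}, seed=6)
        r1 = run_experiment(features, labels, ExperimentConfig(seed=9))
        r2 = run_experiment(features, labels, ExperimentConfig(seed=9))
        assert r1.auc == r2.auc and r1.tp == r2.tp

    def test_summary_table_layout(self):
        features, labels = shifted_null(8, 8, ["a_jit_abs"], {"PD-off": 1.0}, seed=7)
        table = summary_table(
            run_seven_configurations(features, labels, "co-vs-pdoff", seed=7)
        )
        assert len(table) == 7
        assert set(table.columns) >= {"tp", "tn", "fp", "fn", "sensitivity",
                                      "specificity", "accuracy", "auc"}
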