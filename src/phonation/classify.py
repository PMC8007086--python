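"""RBF-kernel SVM experiments over phoneme feature subsets.

Seven classifiers per group contrast, one for each non-empty subset of
the three phonemes {a, o, m} (each phoneme contributes its 12 classifier
features; the mean/median/max/min pitch block is never used).  Evaluation
is stratified 5-fold cross-validation — every fold is an 80/20
train/test split — with features z-scored and the kernel width set by
the median pairwise-distance heuristic on each training fold.  Reported
metrics (confusion counts, sensitivity/specificity/accuracy, ROC, AUC)
are pooled over the out-of-fold predictions.

Split granularity matters: the default 'segment' granularity scatters a
subject's ten segments across folds, so the classifier may partly learn
speaker identity; 'subject' granularity keeps all of a subject's
segments in one fold and gives the honest generalization estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import CLASSIFIER_FEATURES
from .stats import COMPARISONS

__all__ = [
    "ExperimentConfig",
    "ClassificationReport",
    "FEATURE_SUBSETS",
    "make_folds",
    "median_heuristic_gamma",
    "train_eval_svm",
    "roc_auc",
    "run_experiment",
    "run_seven_configurations",
]

FEATURE_SUBSETS = ("a", "o", "m", "a+o", "a+m", "o+m", "a+o+m")

#: positive class per contrast: the more-affected state, so sensitivity
#: means detecting disease (vs CO) or the unmedicated state (vs PD-on).
POSITIVE_CLASS = {
    "pdon-vs-pdoff": "PD-off",
    "co-vs-pdoff": "PD-off",
    "co-vs-pdon": "PD-on",
}


@dataclass(frozen=True)
class ExperimentConfig:
    feature_subset: str = "a+o+m"
    comparison: str = "co-vs-pdoff"
    n_folds: int = 5
    C: float = 1.0
    gamma: float | str = "median"
    tol: float = 1e-3
    granularity: str = "segment"  # or "subject"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_subset not in FEATURE_SUBSETS:
            raise ValueError(f"feature subset must be one of {FEATURE_SUBSETS}")
        if self.comparison not in COMPARISONS:
            raise ValueError(f"unknown comparison {self.comparison!r}")
        if self.granularity not in ("segment", "subject"):
            raise ValueError("granularity must be 'segment' or 'subject'")


@dataclass(frozen=True)
class ClassificationReport:
    feature_subset: str
    comparison: str
    tp: int
    tn: int
    fp: int
    fn: int
    auc: float
    roc: pd.DataFrame
    per_fold: pd.DataFrame
    scores: np.ndarray = field(repr=False, default=None)
    y_true: np.ndarray = field(repr=False, default=None)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / total


def make_folds(y, groups=None, n_folds: int = 5, granularity: str = "segment", seed: int = 0):
    """Stratified disjoint train/test partitions covering every row once.

    At 'subject' granularity all rows sharing a group id stay in one
    fold.  Requires at least ``2 * n_folds`` rows per class.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    if counts.min() < 2 * n_folds:
        raise ValueError(f"smallest class has {counts.min()} rows; need >= {2 * n_folds}")
    if granularity == "subject":
        if groups is None:
            raise ValueError("subject granularity needs group ids")
        splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return list(splitter.split(np.zeros(len(y)), y, groups=groups))
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros(len(y)), y))


def median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF gamma = 1 / (2 sigma^2), sigma = median pairwise distance."""
    from scipy.spatial.distance import pdist

    n = len(X)
    if n > 600:  # deterministic subsample keeps this O(600^2)
        idx = np.linspace(0, n - 1, 600).astype(int)
        X = X[idx]
    d = pdist(X)
    med = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
    return 1.0 / (2.0 * med * med)


def train_eval_svm(X_train, y_train, X_test, config: ExperimentConfig | None = None):
    """Fit a z-scored RBF SVM on the training rows; return continuous
    decision scores and hard labels (threshold 0) for the test rows."""
    config = config or ExperimentConfig()
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training fold contains a single class")
    scaler = StandardScaler().fit(X_train)
    Xs = scaler.transform(X_train)
    gamma = median_heuristic_gamma(Xs) if config.gamma == "median" else config.gamma
    svm = SVC(C=config.C, kernel="rbf", gamma=gamma, tol=config.tol)
    svm.fit(Xs, y_train)
    scores = svm.decision_function(scaler.transform(X_test))
    labels = (scores > 0).astype(int)
    return scores, labels


def roc_auc(scores, y_true) -> tuple[pd.DataFrame, float]:
    """ROC operating points and the area under the curve.

    AUC is the rank (Mann-Whitney) form: the probability that a random
    positive outscores a random negative, ties counted half.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y_true).astype(int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thresholds = roc_curve(y, scores)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return roc, float(auc)


def _subset_columns(columns, subset: str) -> list[str]:
    phonemes = subset.split("+")
    cols = [f"{ph}_{f}" for ph in phonemes for f in CLASSIFIER_FEATURES]
    missing = [c for c in cols if c not in set(columns)]
    if missing:
        raise ValueError(f"dataset lacks columns {missing[:3]}...")
    return cols


def run_experiment(features: pd.DataFrame, labels: pd.Series, config: ExperimentConfig) -> ClassificationReport:
    """One cross-validated SVM for one feature subset and contrast.

    ``features`` rows are indexed by (subject, group, segment); only rows
    of the contrast's two groups are used.
    """
    group_a, group_b, _ = COMPARISONS[config.comparison]
    positive = POSITIVE_CLASS[config.comparison]
    mask = labels.isin([group_a, group_b]).to_numpy()
    cols = _subset_columns(features.columns, config.feature_subset)
    X = features.loc[mask, cols].to_numpy()
    lab = labels[mask]
    y = (lab == positive).astype(int).to_numpy()
    # pairing key: PD-off/PD-on rows of one subject count as one speaker
    subjects = np.asarray(
        [str(s) for s in features.index.get_level_values("subject")[mask]]
    )

    folds = make_folds(y, groups=subjects, n_folds=config.n_folds,
                       granularity=config.granularity, seed=config.seed)
    scores = np.empty(len(y))
    preds = np.empty(len(y), dtype=int)
    fold_rows = []
    for k, (train, test) in enumerate(folds):
        s, p = train_eval_svm(X[train], y[train], X[test], config)
        scores[test] = s
        preds[test] = p
        tp = int(np.sum((p == 1) & (y[test] == 1)))
        tn = int(np.sum((p == 0) & (y[test] == 0)))
        fp = int(np.sum((p == 1) & (y[test] == 0)))
        fn = int(np.sum((p == 0) & (y[test] == 1)))
        fold_rows.append({"fold": k, "n_test": len(test), "tp": tp, "tn": tn,
                          "fp": fp, "fn": fn})
    per_fold = pd.DataFrame(fold_rows)
    roc, auc = roc_auc(scores, y)
    return ClassificationReport(
        feature_subset=config.feature_subset,
        comparison=config.comparison,
        tp=int(per_fold["tp"].sum()),
        tn=int(per_fold["tn"].sum()),
        fp=int(per_fold["fp"].sum()),
        fn=int(per_fold["fn"].sum()),
        auc=auc,
        roc=roc,
        per_fold=per_fold,
        scores=scores,
        y_true=y,
    )


def run_seven_configurations(
    features: pd.DataFrame,
    labels: pd.Series,
    comparison: str,
    seed: int = 0,
    granularity: str = "segment",
) -> dict[str, ClassificationReport]:
    """All seven phoneme-subset SVMs for one contrast.

    Subsets needing a phoneme absent from the feature matrix are skipped,
    so a single-phoneme extraction still yields its one report.
    """
    present = {c.partition("_")[0] for c in features.columns}
    subsets = [s for s in FEATURE_SUBSETS if set(s.split("+")) <= present]
    reports = {}
    for subset in subsets:
        config = ExperimentConfig(
            feature_subset=subset, comparison=comparison, seed=seed,
            granularity=granularity,
        )
        reports[subset] = run_experiment(features, labels, config)
    return reports


def summary_table(reports: dict[str, "ClassificationReport"]) -> pd.DataFrame:
    """Flat metrics table (one row per feature subset)."""
    rows = []
    for subset, rep in reports.items():
        rows.append(
            {
                "feature_subset": subset,
                "comparison": rep.comparison,
                "tp": rep.tp, "tn": rep.tn, "fp": rep.fp, "fn": rep.fn,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "accuracy": rep.accuracy,
                "auc": rep.auc,
            }
        )
    return pd.DataFrame(rows)
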