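"""Nonparametric group comparisons for the cohort feature matrix.

Normality is screened with the Anderson-Darling test; the medication
contrast (PD-on vs PD-off) uses the Wilcoxon signed-rank test on
subject-and-segment-paired rows; the disease contrasts (CO vs either PD
state) use the Mann-Whitney U test.  All tests are two-sided at
alpha = 0.05 with no multiple-testing correction by default (a Holm
option is provided).

The signed-rank exact null distribution is computed in-package by a
generating-function (shift) algorithm over mid-ranks, so exact p-values
remain available for tied data; the large-sample path delegates to
scipy's tie-corrected normal approximation with continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .features import CLASSIFIER_FEATURES, EXCLUDED_PITCH_FEATURES

__all__ = [
    "StatResult",
    "anderson_darling",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "significance_table",
    "COMPARISONS",
]

ALPHA = 0.05
WILCOXON_EXACT_MAX_N = 25
MANNWHITNEY_EXACT_MAX_MIN_N = 8

#: comparison name -> (group_a, group_b, paired)
COMPARISONS = {
    "pdon-vs-pdoff": ("PD-on", "PD-off", True),
    "co-vs-pdoff": ("CO", "PD-off", False),
    "co-vs-pdon": ("CO", "PD-on", False),
}


@dataclass(frozen=True)
class StatResult:
    feature: str
    phoneme: str
    comparison: str
    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def anderson_darling(sample) -> tuple[float, bool]:
    """A2 statistic for the normal family (estimated parameters) and the
    decision at the 5% critical value (True = consistent with normal)."""
    x = np.asarray(sample, dtype=np.float64)
    if len(x) < 8:
        raise ValueError("Anderson-Darling needs n >= 8")
    if np.ptp(x) == 0.0:
        return float("inf"), False  # degenerate constant sample
    res = sst.anderson(x, dist="norm")
    idx = list(res.significance_level).index(5.0)
    crit = res.critical_values[idx]
    return float(res.statistic), bool(res.statistic < crit)


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank sum via the shift algorithm.

    Enumerates the null distribution of W+ over all 2^n sign assignments
    using integer doubled mid-ranks; handles ties exactly.
    """
    doubled = np.round(2.0 * ranks).astype(np.int64)
    total = int(doubled.sum())
    dist = np.zeros(total + 1, dtype=np.float64)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2.0 * w_plus))
    lower = float(dist[: w2 + 1].sum())
    upper = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(lower, upper))


def wilcoxon_signed_rank(
    x, y, feature: str = "", phoneme: str = "", comparison: str = "pdon-vs-pdoff"
) -> StatResult:
    """Two-sided paired signed-rank test.

    Zero differences are dropped (Wilcoxon's original treatment), tied
    absolute differences are mid-ranked.  Exact null distribution for
    n <= 25 retained pairs, tie-corrected normal approximation with
    continuity correction above.  All-zero differences give p = 1 with a
    warning.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return StatResult(feature, phoneme, comparison, "wilcoxon", 0.0, 1.0, (len(x),))
    ranks = sst.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= WILCOXON_EXACT_MAX_N:
        p = _signed_rank_exact_p(ranks, w_plus)
        test = "wilcoxon-exact"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = sst.wilcoxon(
                d, zero_method="wilcox", correction=True, alternative="two-sided",
                method="approx",
            )
        test = "wilcoxon-approx"
    return StatResult(feature, phoneme, comparison, test, w_plus, float(p), (len(x),))


def mann_whitney_u(
    x, y, feature: str = "", phoneme: str = "", comparison: str = "co-vs-pdoff"
) -> StatResult:
    """Two-sided unpaired rank-sum test.

    Exact null distribution when min(n) <= 8 and the pooled data are
    tie-free; tie-corrected normal approximation with continuity
    correction otherwise.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(x), len(y)) <= MANNWHITNEY_EXACT_MAX_MIN_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sst.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return StatResult(
        feature, phoneme, comparison, f"mannwhitney-{method}",
        float(res.statistic), float(res.pvalue), (len(x), len(y)),
    )


def _feature_columns(features: pd.DataFrame):
    names = set(CLASSIFIER_FEATURES) | set(EXCLUDED_PITCH_FEATURES)
    out = []
    for col in features.columns:
        ph, _, name = col.partition("_")
        if name in names:
            out.append((ph, name, col))
    return out


def significance_table(
    dataset,
    comparison: str,
    pitch_extras: pd.DataFrame | None = None,
    aggregate: str = "segment",
    correct: str | None = None,
    feature_columns=None,
) -> pd.DataFrame:
    """Per-(phoneme, feature) test results for one group contrast.

    ``dataset`` is a :class:`~phonation.pipeline.CohortDataset` (or a bare
    features DataFrame indexed by (subject, group, segment), in which case
    ``pitch_extras`` may supply the excluded pitch block).  The paired
    contrast aligns rows by (subject, segment); ``aggregate='subject'``
    first averages the ten segments of each subject, avoiding segment-level
    pseudo-replication.  ``correct='holm'`` adds Holm-adjusted p-values.
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}; one of {list(COMPARISONS)}")
    group_a, group_b, paired = COMPARISONS[comparison]

    if hasattr(dataset, "features"):
        features = dataset.features
        if pitch_extras is None:
            pitch_extras = dataset.pitch_extras
    else:
        features = dataset
    table = features
    if pitch_extras is not None and len(pitch_extras.columns):
        table = pd.concat([features, pitch_extras], axis=1)

    groups = table.index.get_level_values("group")
    for g in (group_a, group_b):
        if g not in set(groups):
            raise ValueError(f"group {g!r} absent from dataset")
    a = table[groups == group_a]
    b = table[groups == group_b]
    if aggregate == "subject":
        a = a.groupby(level="subject").mean()
        b = b.groupby(level="subject").mean()
    elif aggregate != "segment":
        raise ValueError("aggregate must be 'segment' or 'subject'")
    if paired:
        # align by subject (and segment unless aggregated)
        a = a.droplevel("group") if isinstance(a.index, pd.MultiIndex) else a
        b = b.droplevel("group") if isinstance(b.index, pd.MultiIndex) else b
        common = a.index.intersection(b.index)
        a, b = a.loc[common], b.loc[common]

    if feature_columns is None:
        cols = _feature_columns(table)
    else:
        cols = [(c.partition("_")[0], c.partition("_")[2], c) for c in feature_columns]

    rows = []
    for ph, name, col in cols:
        if paired:
            res = wilcoxon_signed_rank(a[col], b[col], name, ph, comparison)
        else:
            res = mann_whitney_u(a[col], b[col], name, ph, comparison)
        rows.append(
            {
                "phoneme": ph,
                "feature": name,
                "comparison": comparison,
                "test": res.test,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "significant": res.significant,
            }
        )
    out = pd.DataFrame(rows)
    if correct == "holm" and len(out):
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, _, _ = multipletests(out["p_value"], alpha=ALPHA, method="holm")
        out["p_holm"] = p_adj
        out["significant_holm"] = reject
    elif correct not in (None, "holm"):
        raise ValueError("correct must be None or 'holm'")
    return out
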