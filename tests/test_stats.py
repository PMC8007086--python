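"""Exact-enumeration oracles and calibration for the group statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from phonation import (
    anderson_darling,
    mann_whitney_u,
    significance_table,
    wilcoxon_signed_rank,
)
from phonation.synth import synthesize_null_features


def wilcoxon_enumeration_p(d: np.ndarray) -> float:
    """Two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = d[d != 0.0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    lower = np.mean(ws <= w_obs + 1e-12)
    upper = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(lower, upper))


def mannwhitney_enumeration_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p by enumerating all C(n+m, n) group assignments."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = rankdata(pooled)

    def u_of(idx):
        return ranks[list(idx)].sum() - n * (n + 1) / 2.0

    u_obs = u_of(range(n))
    us = np.asarray([u_of(c) for c in itertools.combinations(range(n + m), n)])
    # two-sided via distance from the null mean (distribution is symmetric)
    center = n * m / 2.0
    p = np.mean(np.abs(us - center) >= abs(u_obs - center) - 1e-12)
    return min(1.0, float(p))


class TestAndersonDarling:
    def test_normal_samples_pass_most_seeds(self):
        ok = sum(
            anderson_darling(np.random.default_rng(s).standard_normal(500))[1]
            for s in range(20)
        )
        assert ok >= 18  # 5% level: expect ~1 rejection in 20

    def test_exponential_samples_rejected(self):
        for s in range(5):
            x = np.random.default_rng(s).exponential(size=500)
            assert anderson_darling(x)[1] is False

    def test_constant_sample_degenerate(self):
        stat, normal = anderson_darling(np.ones(50))
        assert not normal and math.isinf(stat)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            anderson_darling(np.arange(5.0))


class TestWilcoxon:
    def test_all_positive_differences_exact_p(self):
        # n=6 all-positive differences: two-sided p = 2/2^6
        res = wilcoxon_signed_rank(np.arange(1.0, 7.0), np.zeros(6))
        assert res.p_value == pytest.approx(2.0 / 64.0, rel=1e-12)

    def test_identical_pairs_p_one(self):
        x = np.arange(10.0)
        with pytest.warns(UserWarning):
            res = wilcoxon_signed_rank(x, x)
        assert res.p_value == 1.0
        assert not res.significant

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal(12), rng.standard_normal(12)
        assert wilcoxon_signed_rank(x, y).p_value == pytest.approx(
            wilcoxon_signed_rank(y, x).p_value, rel=1e-12
        )

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        if seed % 3 == 0:  # force tied |differences|
            y[1] = x[1] - (x[0] - y[0])
        res = wilcoxon_signed_rank(x, y)
        assert res.p_value == pytest.approx(wilcoxon_enumeration_p(x - y), rel=1e-10)

    def test_scipy_agreement_large_n(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(8)
        x = rng.standard_normal(60)
        y = rng.standard_normal(60) + 0.3
        res = wilcoxon_signed_rank(x, y)
        _, p_ref = scipy_wilcoxon(x - y, correction=True, method="approx")
        assert res.p_value == pytest.approx(p_ref, rel=1e-10)


class TestMannWhitney:
    def test_fully_separated_toy_exact_p(self):
        # x=[1,2,3], y=[4,5,6]: U=0, two-sided p = 2/C(6,3) = 0.1
        res = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1, rel=1e-12)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal(8), rng.standard_normal(10)
        assert mann_whitney_u(x, y).p_value == pytest.approx(
            mann_whitney_u(y, x).p_value, rel=1e-12
        )

    def test_identical_multisets_p_near_one(self):
        x = np.array([1.0, 2.0, 2.0, 3.0] * 8)
        res = mann_whitney_u(x, x.copy())
        assert res.p_value > 0.9

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_small_n(self, seed):
        rng = np.random.default_rng(100 + seed)
        n, m = int(rng.integers(3, 8)), int(rng.integers(3, 8))
        x = rng.standard_normal(n)
        y = rng.standard_normal(m)
        res = mann_whitney_u(x, y)
        assert res.p_value == pytest.approx(mannwhitney_enumeration_p(x, y), rel=1e-10)

    def test_p_monotone_in_location_shift(self):
        """Starting from identical groups, a growing location shift can
        only push the rank-sum p-value down."""
        rng = np.random.default_rng(9)
        x = rng.standard_normal(30)
        ps = [
            mann_whitney_u(x, x + shift).p_value
            for shift in np.linspace(0.0, 2.0, 9)
        ]
        assert ps[0] > 0.9
        assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))


class TestSignificanceTable:
    def test_strong_effects_all_significant(self):
        features, labels = synthesize_null_features(12, 12, seed=0)
        # inject a strong location shift into every PD-off column
        mask = features.index.get_level_values("group") == "PD-off"
        features.loc[mask] += 3.0
        table = significance_table(features, "co-vs-pdoff")
        assert table["significant"].all()
        assert len(table) == 3 * 16

    def test_paired_contrast_uses_wilcoxon(self):
        features, _ = synthesize_null_features(6, 6, seed=1)
        table = significance_table(features, "pdon-vs-pdoff")
        assert table["test"].str.startswith("wilcoxon").all()

    def test_subject_aggregation_reduces_n(self):
        features, _ = synthesize_null_features(8, 8, seed=2)
        mask = features.index.get_level_values("group") == "PD-off"
        features.loc[mask, features.columns[0]] += 0.4
        seg = significance_table(features, "co-vs-pdoff", aggregate="segment")
        sub = significance_table(features, "co-vs-pdoff", aggregate="subject")
        # pseudo-replication at segment level yields smaller p for a real shift
        assert seg.loc[0, "p_value"] < sub.loc[0, "p_value"]

    def test_holm_correction_is_more_conservative(self):
        features, _ = synthesize_null_features(10, 10, seed=3)
        table = significance_table(features, "co-vs-pdon", correct="holm")
        assert (table["p_holm"] >= table["p_value"] - 1e-15).all()
        assert table["significant_holm"].sum() <= table["significant"].sum()

    def test_empty_feature_list_gives_empty_table(self):
        features, _ = synthesize_null_features(6, 6, seed=4)
        table = significance_table(features, "co-vs-pdoff", feature_columns=[])
        assert len(table) == 0

    def test_missing_group_rejected(self):
        features, _ = synthesize_null_features(6, 0, seed=5)
        with pytest.raises(ValueError):
            significance_table(features, "co-vs-pdoff")
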