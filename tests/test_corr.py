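"""Group comparison: Welch's t, the permutation test (checked against an
exhaustive enumeration oracle and a scipy cross-check), the comparison
table layout and feature selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eegsa import corr


class TestWelchT:
    def test_identical_samples(self):
        assert corr.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_value(self):
        assert corr.welch_t([1, 2, 3], [2, 3, 4]) == pytest.approx(-1.2247, abs=1e-4)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=5)
        assert corr.welch_t(a, b) == pytest.approx(-corr.welch_t(b, a))

    def test_matches_scipy_closed_form(self, rng):
        for _ in range(20):
            a = rng.normal(size=int(rng.integers(2, 30)))
            b = rng.normal(1.0, 2.0, size=int(rng.integers(2, 30)))
            expected = stats.ttest_ind(a, b, equal_var=False).statistic
            assert corr.welch_t(a, b) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_variances(self):
        assert corr.welch_t([2.0, 2.0], [2.0, 2.0]) == 0.0
        assert corr.welch_t([3.0, 3.0], [2.0, 2.0]) == np.inf

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            corr.welch_t([1.0], [1.0, 2.0])


class TestPermutationP:
    def test_identical_values_give_p_one(self):
        assert corr.permutation_p(np.ones(6), np.ones(6), n_perm=200, seed=0) == 1.0

    def test_lower_bound(self):
        a = np.array([10.0, 11.0, 12.0])
        b = np.array([0.0, 0.5, 1.0])
        p = corr.permutation_p(a, b, n_perm=99, seed=0)
        assert p >= 1 / 100

    def test_matches_exhaustive_split_oracle(self):
        a = np.array([3.1, 4.0, 5.2])
        b = np.array([1.0, 1.5, 2.2])
        pooled = np.concatenate([a, b])
        t_obs = abs(corr.welch_t(a, b))
        # oracle: all C(6,3)=20 label splits
        count = 0
        splits = list(itertools.combinations(range(6), 3))
        for ia in splits:
            ib = [i for i in range(6) if i not in ia]
            if abs(corr.welch_t(pooled[list(ia)], pooled[ib])) >= t_obs - 1e-12:
                count += 1
        p_exact = count / len(splits)
        p_mc = corr.permutation_p(a, b, n_perm=4000, seed=1)
        # Monte-Carlo error ~ sqrt(p(1-p)/n) ≈ 0.006 here
        assert p_mc == pytest.approx(p_exact, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            corr.permutation_p(np.array([]), np.array([1.0]), n_perm=10)

    def test_null_type_one_error_calibrated(self):
        # light version of the calibration suite (full run in acceptance)
        rng = np.random.default_rng(123)
        hits = 0
        n_sim = 120
        for _ in range(n_sim):
            a = rng.normal(size=13)
            b = rng.normal(size=12)
            if corr.permutation_p(a, b, n_perm=199, seed=int(rng.integers(2**31))) < 0.05:
                hits += 1
        assert hits / n_sim == pytest.approx(0.05, abs=0.05)


def _toy_subject_table(rng, shift_pairs=(), n_high=4, n_low=4):
    rows = []
    for metric in corr.METRICS:
        for region in ("F", "C", "P", "O"):
            delta = 1.0 if (metric, region) in shift_pairs else 0.0
            for i in range(n_high):
                rows.append({"subject_id": f"H{i}", "group": "high",
                             "metric": metric, "region": region,
                             "value": rng.normal(0.0, 0.1)})
            for i in range(n_low):
                rows.append({"subject_id": f"L{i}", "group": "low",
                             "metric": metric, "region": region,
                             "value": rng.normal(delta, 0.1)})
    return pd.DataFrame(rows)


class TestEvaluateCorrelations:
    def test_five_metrics_by_four_regions(self, rng):
        table = _toy_subject_table(rng)
        out = corr.evaluate_correlations(table, n_perm=99, seed=0)
        assert len(out) == 20
        assert set(out.columns) >= {"metric", "region", "mean_high", "std_high",
                                    "mean_low", "std_low", "t", "p"}

    def test_missing_region_named_in_error(self, rng):
        table = _toy_subject_table(rng)
        table = table[table["region"] != "O"]
        with pytest.raises(ValueError, match="O"):
            corr.evaluate_correlations(table, n_perm=9, seed=0)

    def test_planted_shift_found(self, rng):
        table = _toy_subject_table(
            rng, shift_pairs={("alpha/beta", "F")}, n_high=8, n_low=8
        )
        out = corr.evaluate_correlations(table, n_perm=499, seed=0)
        hit = out[(out["metric"] == "alpha/beta") & (out["region"] == "F")]
        # the planted pair reaches the Monte-Carlo significance floor
        assert float(hit["p"].iloc[0]) <= 0.01
        others = out[(out["metric"] != "alpha/beta") | (out["region"] != "F")]
        assert (others["p"] > 0.01).mean() >= 0.9

    def test_subject_means_layout(self, small_features):
        tidy = corr.subject_means(small_features)
        assert set(tidy.columns) == {"subject_id", "group", "metric", "region", "value"}
        # 8 subjects x 5 metrics x 4 regions
        assert len(tidy) == 8 * 5 * 4


class TestSelectFeatures:
    def _comparisons(self, sig_pairs):
        rows = []
        for metric in corr.METRICS:
            for region in ("F", "C", "P", "O"):
                rows.append({"metric": metric, "region": region,
                             "p": 0.01 if (metric, region) in sig_pairs else 0.5})
        return pd.DataFrame(rows)

    def test_full_trio_yields_twelve_names(self):
        sig = {(m, r) for m in corr.CORRELATED_METRICS for r in ("F", "C")}
        names = corr.select_features(self._comparisons(sig))
        assert names == [
            "FM1", "FP1", "CM1", "CP1",
            "FM2", "FP2", "CM2", "CP2",
            "FM3", "FP3", "CM3", "CP3",
        ]

    def test_no_significant_pairs(self):
        assert corr.select_features(self._comparisons(set())) == []

    def test_one_pair_gives_mean_and_median(self):
        names = corr.select_features(self._comparisons({("alpha/beta", "C")}))
        assert names == ["CM1", "CP1"]

    def test_significant_outside_selection_regions_ignored(self):
        sig = {("alpha/beta", "P"), ("theta/(alpha+theta)", "O")}
        assert corr.select_features(self._comparisons(sig)) == []

    def test_size_is_twice_pair_count(self, rng):
        for _ in range(10):
            k = int(rng.integers(0, 7))
            pairs = set()
            pool = [(m, r) for m in corr.CORRELATED_METRICS for r in ("F", "C")]
            idx = rng.choice(len(pool), size=k, replace=False)
            pairs = {pool[i] for i in idx}
            assert len(corr.select_features(self._comparisons(pairs))) == 2 * k
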