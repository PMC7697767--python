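import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sdmlite.bioclim import BioclimEnvelope
from sdmlite.evaluation import (apply_threshold, evaluate_scores,
                                max_sss_threshold, permutation_importance,
                                roc_auc, summarize_occurrence_climate)


def auc_pairwise(p, a):
    """O(n_p * n_a) oracle straight from the pair definition."""
    wins = sum(1.0 if x > y else 0.5 if x == y else 0.0
               for x, y in itertools.product(p, a))
    return wins / (len(p) * len(a))


def maxsss_oracle(p, a):
    """Exhaustive scan over every distinct observed score."""
    best = None
    for t in sorted(set(p) | set(a)):
        sens = np.mean([x >= t for x in p])
        spec = np.mean([x < t for x in a])
        if best is None or sens + spec > best[1] + best[2] + 1e-12:
            best = (t, sens, spec)
    return best


class TestAUC:
    @pytest.mark.parametrize("p,a,expected", [
        ([0.9, 0.8, 0.6], [0.3, 0.2, 0.5], 1.0),
        ([0.7, 0.7], [0.7, 0.7, 0.7], 0.5),
        ([0.9, 0.8, 0.4], [0.3, 0.2, 0.7], 8.0 / 9.0),
    ])
    def test_examples(self, p, a, expected):
        assert roc_auc(p, a) == pytest.approx(expected)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            p = rng.integers(0, 10, size=rng.integers(1, 51)) / 10.0
            a = rng.integers(0, 10, size=rng.integers(1, 51)) / 10.0
            assert roc_auc(p, a) == pytest.approx(auc_pairwise(p, a))

    def test_complementarity(self):
        rng = np.random.default_rng(1)
        p = rng.normal(size=40)
        a = rng.normal(size=60)
        assert roc_auc(p, a) + roc_auc(a, p) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [0.5])

    scores = st.lists(st.integers(0, 12).map(lambda v: v / 12.0),
                      min_size=1, max_size=30)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(p=scores, a=scores)
    def test_pairwise_oracle_and_complementarity_property(self, p, a):
        assert roc_auc(p, a) == pytest.approx(auc_pairwise(p, a))
        assert roc_auc(p, a) + roc_auc(a, p) == pytest.approx(1.0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(p=scores, a=scores)
    def test_maxsss_matches_oracle_property(self, p, a):
        assert max_sss_threshold(p, a) == pytest.approx(maxsss_oracle(p, a))


class TestMaxSSS:
    def test_perfect_separation(self):
        t, sens, spec = max_sss_threshold([0.9, 0.8, 0.6], [0.3, 0.2, 0.5])
        assert (t, sens, spec) == (0.6, 1.0, 1.0)

    def test_tie_breaks_to_smallest_threshold(self):
        t, sens, spec = max_sss_threshold([0.9, 0.8, 0.4], [0.3, 0.2, 0.7])
        assert t == 0.4
        assert sens + spec == pytest.approx(5.0 / 3.0)

    def test_single_scores(self):
        assert max_sss_threshold([0.5], [0.5]) == (0.5, 1.0, 0.0)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            p = list(rng.integers(0, 8, size=rng.integers(1, 30)) / 8.0)
            a = list(rng.integers(0, 8, size=rng.integers(1, 30)) / 8.0)
            got = max_sss_threshold(p, a)
            want = maxsss_oracle(p, a)
            assert got == pytest.approx(want)

    def test_gaussian_midpoint_recovery(self):
        # equal-variance Gaussians: the optimal rule is the midpoint of the
        # means.  The empirical maximizer converges at the cube-root rate, so
        # check the typical (median over seeds) error shrinks with n and is
        # inside 0.05 by n = 40,000
        def median_error(n):
            errors = []
            for seed in range(9):
                rng = np.random.default_rng(seed)
                p = rng.normal(1.0, 1.0, size=n)
                a = rng.normal(-1.0, 1.0, size=n)
                t, _, _ = max_sss_threshold(p, a)
                errors.append(abs(t - 0.0))
            return np.median(errors)

        coarse, fine = median_error(2500), median_error(40000)
        assert fine < coarse
        assert fine < 0.05


class TestApplyThreshold:
    def test_zero_threshold_on_nonnegative_grid(self):
        grid = np.array([[0.0, 0.5], [np.nan, 1.0]])
        out = apply_threshold(grid, 0.0)
        np.testing.assert_array_equal(out, [[1.0, 1.0], [np.nan, 1.0]])

    def test_threshold_above_maximum(self):
        grid = np.array([[0.1, 0.2]])
        np.testing.assert_array_equal(apply_threshold(grid, 0.5), [[0.0, 0.0]])

    def test_cellwise_rule_on_mixed_grid(self):
        grid = np.array([[0.1, 0.5, 0.9],
                         [0.5, np.nan, 0.2],
                         [0.7, 0.4, 0.5]])
        out = apply_threshold(grid, 0.5)
        np.testing.assert_array_equal(
            out, [[0, 1, 1], [1, np.nan, 0], [1, 0, 1]])


class TestPermutationImportance:
    @staticmethod
    def _table(seed=0, n=300):
        rng = np.random.default_rng(seed)
        data = pd.DataFrame({
            "lon": np.zeros(n), "lat": np.zeros(n),
            "label": (rng.uniform(size=n) < 0.3).astype(int),
            "a": rng.normal(size=n), "b": rng.normal(size=n),
        })
        data.loc[data["label"] == 1, "a"] += 2.0
        return data

    def test_ignored_variable_scores_zero(self):
        data = self._table()

        class OnlyA:
            variables_ = ["a", "b"]

            def predict(self, X):
                return X["a"].to_numpy(dtype=float)

        table = permutation_importance(OnlyA(), data, n_reps=3, seed=1)
        assert table.set_index("variable").loc["b", "importance_pct"] == 0.0
        assert table.set_index("variable").loc["a", "importance_pct"] == 100.0

    def test_single_variable_model_gets_all_importance(self):
        data = self._table()[["lon", "lat", "label", "a"]]
        model = BioclimEnvelope().fit(data.loc[data["label"] == 1, ["a"]])
        table = permutation_importance(model, data, n_reps=3, seed=2)
        assert table["importance_pct"].iloc[0] == pytest.approx(100.0)

    def test_importances_sum_to_100(self):
        data = self._table(seed=5)
        model = BioclimEnvelope().fit(data.loc[data["label"] == 1, ["a", "b"]])
        table = permutation_importance(model, data, n_reps=5, seed=3)
        assert table["importance_pct"].sum() == pytest.approx(100.0, abs=1e-6)
        assert (table["importance_pct"] >= 0).all()


class TestSummary:
    def test_constant_column(self):
        data = pd.DataFrame({"label": [1, 1, 1], "a": [2.0, 2.0, 2.0]})
        out = summarize_occurrence_climate(data)
        assert out["a"]["min"] == out["a"]["max"] == out["a"]["mean"] == 2.0
        assert sum(1 for c in out["a"]["counts"] if c > 0) == 1

    def test_range_and_mean(self):
        data = pd.DataFrame({"label": np.ones(11, int),
                             "a": np.arange(11, dtype=float)})
        out = summarize_occurrence_climate(data)
        assert (out["a"]["min"], out["a"]["max"], out["a"]["mean"]) == (0, 10, 5)

    def test_counts_conserve_rows(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame({"label": np.ones(57, int),
                             "a": rng.normal(size=57)})
        out = summarize_occurrence_climate(data)
        assert sum(out["a"]["counts"]) == 57


class TestEvalReport:
    def test_report_fields_consistent(self):
        rng = np.random.default_rng(5)
        p = rng.normal(1, 1, 200)
        a = rng.normal(0, 1, 300)
        rep = evaluate_scores(p, a)
        assert 0 <= rep.auc <= 1
        t, sens, spec = max_sss_threshold(p, a)
        assert rep.threshold_maxsss == t
        assert rep.sens_at_t == sens and rep.spec_at_t == spec
        assert {"threshold", "sensitivity", "specificity"} <= set(rep.roc.columns)
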