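"""ROC/AUC, DeLong intervals, Youden cutoffs, logistic fits, cutpoint scans."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ihcscore import (
    cutpoint_scan,
    group_summary,
    logistic_association,
    pairwise_group_auc,
    pooled_mean,
    roc_curve,
    youden_cutoff,
)
from ihcscore.stats import SingleClassError

from conftest import exhaustive_youden, pair_count_auc

# Frozen independent oracle: R pROC roc()/ci.auc(method="delong") on this
# 12-case fixture (direction "<", i.e. higher score = positive call).
PROC_SCORES = [0.1, 0.2, 0.35, 0.4, 0.55, 0.6, 0.7, 0.8, 0.9, 1.2, 1.3, 1.5]
PROC_LABELS = [0, 0, 1, 0, 0, 1, 0, 1, 1, 0, 1, 1]
PROC_AUC = 0.7777777778
PROC_SE = 0.1448711646
PROC_CI = (0.4938355128, 1.0)


# a small labelled sample guaranteed to contain both classes
@st.composite
def small_roc_inputs(draw):
    n = draw(st.integers(4, 12))
    scores = draw(st.lists(st.integers(0, 8).map(float), min_size=n, max_size=n))
    n_pos = draw(st.integers(1, n - 1))
    labels = [1] * n_pos + [0] * (n - n_pos)
    return np.array(scores), np.array(labels)


class TestRoc:
    def test_perfect_separation_gives_auc_one(self):
        roc = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc.auc == 1.0
        assert roc.sens_at_cutoff == 1.0 and roc.spec_at_cutoff == 1.0
        assert 3 < roc.youden_cutoff <= 10

    def test_shuffled_labels_give_null_auc(self, rng):
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, size=4000)
        assert roc_curve(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            roc_curve([1.0, 2.0], [1, 1])

    def test_matches_frozen_delong_oracle(self):
        roc = roc_curve(PROC_SCORES, PROC_LABELS)
        assert roc.auc == pytest.approx(PROC_AUC, abs=1e-9)
        assert roc.auc_se == pytest.approx(PROC_SE, abs=1e-9)
        assert roc.auc_ci95[0] == pytest.approx(PROC_CI[0], abs=1e-9)
        assert roc.auc_ci95[1] == pytest.approx(PROC_CI[1], abs=1e-9)

    def test_matches_sklearn_with_ties(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.integers(0, 10, size=300).astype(float)  # heavy ties
        labels = rng.integers(0, 2, size=300)
        assert roc_curve(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    @given(small_roc_inputs())
    @settings(max_examples=100, derandomize=True)
    def test_auc_equals_exhaustive_pair_counting(self, inputs):
        scores, labels = inputs
        assert roc_curve(scores, labels).auc == pytest.approx(
            pair_count_auc(scores, labels), abs=1e-12)

    @given(small_roc_inputs())
    @settings(max_examples=60, derandomize=True)
    def test_invariant_under_monotone_transform(self, inputs):
        scores, labels = inputs
        base = roc_curve(scores, labels)
        for f in (lambda s: 2.0 * s + 1.0, np.exp):
            assert roc_curve(f(scores), labels).auc == pytest.approx(base.auc, abs=1e-12)

    @given(small_roc_inputs())
    @settings(max_examples=60, derandomize=True)
    def test_score_negation_symmetry(self, inputs):
        scores, labels = inputs
        a = roc_curve(scores, labels).auc
        b = roc_curve(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_delong_se_shrinks_with_sample_size(self, rng):
        ses = []
        for n in (50, 500, 5000):
            scores = np.r_[rng.normal(0, 1, n), rng.normal(0.8, 1, n)]
            labels = np.r_[np.zeros(n), np.ones(n)]
            ses.append(roc_curve(scores, labels).auc_se)
        assert ses[0] > ses[1] > ses[2]


class TestYouden:
    def test_hand_worked_example(self):
        roc = roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        cut, sens, spec = youden_cutoff(roc)
        assert (cut, sens, spec) == (3.0, 1.0, 1.0)

    @given(small_roc_inputs())
    @settings(max_examples=100, derandomize=True)
    def test_matches_exhaustive_search(self, inputs):
        scores, labels = inputs
        roc = roc_curve(scores, labels)
        cut, sens, spec = youden_cutoff(roc)
        ecut, esens, espec = exhaustive_youden(scores, labels)
        assert cut == ecut
        assert sens == pytest.approx(esens) and spec == pytest.approx(espec)


class TestLogistic:
    @staticmethod
    def _cohort(scores, labels):
        return pd.DataFrame({"fish_status": labels, "hscore": scores})

    def test_intercept_only_recovers_prevalence(self):
        labels = np.r_[np.ones(13), np.zeros(169)]
        fit = logistic_association(self._cohort(np.zeros(182), labels), predictors=())
        b0 = fit.terms.loc["const", "coef"]
        assert 1 / (1 + np.exp(-b0)) == pytest.approx(13 / 182, abs=1e-6)

    def test_zero_variance_predictor_dropped(self):
        labels = np.r_[np.ones(10), np.zeros(10)]
        fit = logistic_association(self._cohort(np.full(20, 2.5), labels))
        assert fit.dropped == ("hscore",)
        assert "hscore" not in fit.terms.index

    def test_perfect_separation_flagged_not_crashed(self):
        labels = np.r_[np.zeros(10), np.ones(10)]
        scores = np.r_[np.arange(10), np.arange(20, 30)].astype(float)
        fit = logistic_association(self._cohort(scores, labels))
        assert not fit.converged

    def test_ci_contains_odds_ratio(self, rng):
        x = rng.normal(size=400)
        p = 1 / (1 + np.exp(-(0.5 * x)))
        y = rng.random(400) < p
        fit = logistic_association(self._cohort(x, y.astype(int)))
        t = fit.terms.loc["hscore"]
        assert t["ci_low"] <= t["odds_ratio"] <= t["ci_high"]
        assert t["odds_ratio"] > 0


class TestCutpointScan:
    def test_adjusted_p_is_bonferroni_of_raw(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        scan = cutpoint_scan(scores, labels)
        expected = np.minimum(1.0, scan.table["p_raw"] * scan.n_tests)
        assert np.allclose(scan.table["p_adj"], expected)
        assert (scan.table["p_adj"] >= scan.table["p_raw"] - 1e-15).all()

    def test_perfect_separation_found_significant(self):
        scores = np.r_[np.linspace(0, 1, 10), np.linspace(5, 6, 10)]
        labels = np.r_[np.zeros(10), np.ones(10)]
        scan = cutpoint_scan(scores, labels)
        assert 1.0 < scan.best_cutpoint < 5.0
        assert scan.best_p_adj < 0.05

    def test_out_of_range_candidates_skipped(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        grid = [scores.min() - 1.0, 0.0, scores.max() + 1.0]
        scan = cutpoint_scan(scores, labels, grid=grid)
        assert set(scan.skipped) == {scores.min() - 1.0, scores.max() + 1.0}
        assert scan.n_tests == 1

    @pytest.mark.parametrize("test", ["chisq", "fisher"])
    def test_alternative_tests_available(self, test, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        scan = cutpoint_scan(scores, labels, test=test)
        assert ((scan.table["p_raw"] >= 0) & (scan.table["p_raw"] <= 1)).all()

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            cutpoint_scan(np.ones(10), np.r_[np.ones(5), np.zeros(5)])


class TestPairwiseAuc:
    def test_stochastic_dominance_gives_auc_above_half(self, rng):
        df = pd.DataFrame({
            "ihc_category": np.r_[np.full(100, 2), np.full(100, 3)],
            "hscore": np.r_[rng.normal(2.6, 0.9, 100), rng.normal(4.0, 1.4, 100) + 1],
        })
        table = pairwise_group_auc(df)
        assert table.loc[table.comparison == "3 vs 2", "auc"].item() >= 0.5

    def test_identical_distributions_give_null_auc(self, rng):
        df = pd.DataFrame({
            "ihc_category": np.r_[np.full(200, 0), np.full(200, 1)],
            "hscore": rng.normal(3.0, 1.0, 400),
        })
        row = pairwise_group_auc(df).iloc[0]
        assert abs(row["auc"] - 0.5) < 3 * row["se"]

    def test_all_pairs_emitted_in_category_order(self, rng):
        df = pd.DataFrame({
            "ihc_category": np.repeat([0, 1, 2, 3], 10),
            "hscore": rng.normal(3.0, 1.0, 40),
        })
        table = pairwise_group_auc(df)
        assert list(table.comparison) == [
            "1 vs 0", "2 vs 0", "3 vs 0", "2 vs 1", "3 vs 1", "3 vs 2"]

    def test_tiny_category_skipped(self, rng):
        df = pd.DataFrame({
            "ihc_category": np.r_[np.full(10, 2), np.full(10, 3), [0]],
            "hscore": rng.normal(3.0, 1.0, 21),
        })
        table = pairwise_group_auc(df)
        assert list(table.comparison) == ["3 vs 2"]


class TestGroupSummary:
    def test_single_case_group_has_undefined_sd(self):
        df = pd.DataFrame({"ihc_category": [0], "hscore": [3.0],
                           "mean_intensity": [np.nan], "pct_area": [np.nan]})
        row = group_summary(df).iloc[0]
        assert np.isnan(row["hscore_sd"])
        assert row["hscore_min"] == row["hscore_max"] == 3.0

    def test_weighted_recombination_of_group_means(self):
        # overall mean from (n, mean) per FISH group
        assert round(pooled_mean([169, 13], [2.62, 3.06]), 2) == 2.65
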