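import itertools

import numpy as np
import pytest
from scipy import stats

from radrec.classify import (
    GREATER,
    LESSER,
    ConjunctionRuleClassifier,
    PAPER_RULE,
    StepwiseLogisticRegression,
    ThresholdRule,
    YoudenThresholdClassifier,
    apply_rule,
    best_cutoff,
    confusion_metrics,
    delong_compare,
    fisher_exact,
    group_compare,
    loocv_accuracy,
    rater_agreement,
    roc_analysis,
    stepwise_logistic,
)
from radrec.types import CohortTable, LesionFeatures, PatientRecord, ValidationError


def auc_oracle(pos, neg):
    """O(n²) concordance count: P(pos > neg) + ½P(tie)."""
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def labels_from(pos, neg):
    scores = np.concatenate([pos, neg])
    y = np.array(["recurrence"] * len(pos) + ["radionecrosis"] * len(neg))
    return scores, y


class TestROC:
    def test_perfect_separation(self):
        scores, y = labels_from([3.0, 4.0, 5.0], [1.0, 2.0])
        assert roc_analysis(scores, y).auc == 1.0

    def test_uninformative_constant_scores(self):
        scores, y = labels_from([1.0] * 5, [1.0] * 5)
        assert roc_analysis(scores, y).auc == 0.5

    def test_auc_equals_concordance_oracle(self, rng):
        for _ in range(200):
            pos = rng.normal(1, 1, size=rng.integers(3, 20))
            neg = rng.normal(0, 1, size=rng.integers(3, 20))
            scores, y = labels_from(pos, neg)
            assert roc_analysis(scores, y).auc == pytest.approx(
                auc_oracle(pos, neg), abs=1e-12
            )

    def test_lesser_direction_flips(self, rng):
        pos = rng.normal(0, 1, 10)
        neg = rng.normal(1, 1, 10)
        scores, y = labels_from(pos, neg)
        assert roc_analysis(scores, y, direction=LESSER).auc == pytest.approx(
            auc_oracle(-pos, -neg), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_analysis([1.0, 2.0], ["recurrence", "recurrence"])


def cutoff_oracle(scores, y, direction):
    """Exhaustive threshold scan maximizing Youden's J."""
    best = (-np.inf, None)
    for t in np.concatenate([[-np.inf], np.unique(scores)]):
        pred = scores > t if direction == GREATER else scores <= t
        pos = y == "recurrence"
        sens = (pred & pos).sum() / pos.sum()
        spec = (~pred & ~pos).sum() / (~pos).sum()
        j = sens + spec - 1
        if j > best[0] + 1e-12:
            best = (j, t)
    return best[0]


class TestBestCutoff:
    def test_separable_case_classifies_all(self):
        scores, y = labels_from([3.0, 4.0, 5.0], [1.0, 2.0])
        res = best_cutoff(roc_analysis(scores, y))
        assert 2.0 <= res.cutoff < 3.0
        assert np.all((scores > res.cutoff) == (y == "recurrence"))
        assert res.youden_j == pytest.approx(1.0)

    def test_all_equal_scores_degenerate(self):
        scores, y = labels_from([2.0, 2.0], [2.0, 2.0, 2.0])
        res = best_cutoff(roc_analysis(scores, y))
        assert res.degenerate and res.youden_j == pytest.approx(0.0)

    @pytest.mark.parametrize("direction", [GREATER, LESSER])
    def test_matches_exhaustive_scan(self, direction, rng):
        for _ in range(200):
            pos = rng.normal(1, 1, size=rng.integers(3, 15))
            neg = rng.normal(0, 1, size=rng.integers(3, 15))
            scores, y = labels_from(pos, neg)
            res = best_cutoff(roc_analysis(scores, y, direction=direction))
            assert res.youden_j == pytest.approx(
                cutoff_oracle(scores, y, direction), abs=1e-9
            )


class TestConjunctionRule:
    def _features(self, ncbv90, pro):
        return LesionFeatures(1.0, 0.5, ncbv90, ncbv90, ncbv90, pro)

    def test_group_mean_profile_is_recurrence(self):
        # published recurrence-group means fall on the recurrence side
        assert apply_rule(self._features(5.98, 9.3), PAPER_RULE) == "recurrence"

    def test_boundary_is_strict(self):
        assert apply_rule(self._features(2.07, 10.0), PAPER_RULE) == "radionecrosis"

    def test_hemorrhage_overrides_high_perfusion(self):
        assert apply_rule(self._features(5.0, 40.0), PAPER_RULE) == "radionecrosis"

    def test_extreme_rules(self, rng):
        ncbv = rng.uniform(0, 10, 20)
        pro = rng.uniform(0, 100, 20)
        all_pos = ThresholdRule(-np.inf, 100.0).decide(ncbv, pro)
        assert np.all(all_pos == "recurrence")
        all_neg = ThresholdRule(np.inf, 100.0).decide(ncbv, pro)
        assert np.all(all_neg == "radionecrosis")

    def test_estimator_derives_separating_cutoffs(self):
        X = np.array([[5.0, 5.0], [6.0, 8.0], [4.0, 2.0], [1.0, 50.0], [1.5, 60.0]])
        y = np.array(["recurrence"] * 3 + ["radionecrosis"] * 2)
        clf = ConjunctionRuleClassifier().fit(X, y)
        assert np.all(clf.predict(X) == y)


class TestConfusionMetrics:
    def test_published_sensitivity_fraction(self):
        y = np.array(["recurrence"] * 32 + ["radionecrosis"] * 19)
        pred = np.array(["recurrence"] * 23 + ["radionecrosis"] * 9 + ["radionecrosis"] * 19)
        cm = confusion_metrics(pred, y)
        assert cm.sensitivity == pytest.approx(100 * 23 / 32)
        assert round(cm.sensitivity, 1) == 71.9

    def test_all_correct(self):
        y = np.array(["recurrence", "radionecrosis"] * 3)
        cm = confusion_metrics(y.copy(), y)
        assert (cm.sensitivity, cm.specificity, cm.accuracy) == (100.0, 100.0, 100.0)

    def test_published_single_variable_row(self):
        # 28 TP, 4 FN, 14 TN, 5 FP → 87.5 / 73.7 / 82.3
        y = ["recurrence"] * 32 + ["radionecrosis"] * 19
        pred = (
            ["recurrence"] * 28 + ["radionecrosis"] * 4
            + ["radionecrosis"] * 14 + ["recurrence"] * 5
        )
        cm = confusion_metrics(np.array(pred), np.array(y))
        assert round(cm.sensitivity, 1) == 87.5
        assert round(cm.specificity, 1) == 73.7
        assert cm.accuracy == pytest.approx(100 * 42 / 51)


class TestDeLong:
    def test_identical_scores(self, rng):
        scores = rng.normal(size=30)
        y = np.array(["recurrence"] * 15 + ["radionecrosis"] * 15)
        res = delong_compare(scores, scores.copy(), y)
        assert res.auc_a == res.auc_b
        assert res.p_value == 1.0

    def test_aucs_match_roc_analysis(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        y = np.array(["recurrence"] * 18 + ["radionecrosis"] * 22)
        res = delong_compare(a, b, y)
        assert res.auc_a == pytest.approx(roc_analysis(a, y).auc, abs=1e-12)
        assert res.auc_b == pytest.approx(roc_analysis(b, y).auc, abs=1e-12)

    def test_variance_against_bootstrap(self, rng):
        """DeLong variance of the AUC difference agrees with a 2000-resample
        bootstrap within 15% relative on an n=51-style dataset."""
        n_pos, n_neg = 32, 19
        x = rng.normal(size=n_pos + n_neg)
        a = x + rng.normal(0, 0.5, size=x.size) + np.r_[np.ones(n_pos), np.zeros(n_neg)]
        b = x + rng.normal(0, 0.5, size=x.size) + 0.8 * np.r_[np.ones(n_pos), np.zeros(n_neg)]
        y = np.array(["recurrence"] * n_pos + ["radionecrosis"] * n_neg)
        from radrec.classify import _as_binary, _delong_covariance

        yb, _ = _as_binary(y)
        _, cov = _delong_covariance([a, b], yb)
        var_delong = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
        diffs = []
        idx_pos = np.arange(n_pos)
        idx_neg = np.arange(n_pos, n_pos + n_neg)
        for _ in range(2000):
            bp = rng.choice(idx_pos, n_pos)
            bn = rng.choice(idx_neg, n_neg)
            sel = np.concatenate([bp, bn])
            diffs.append(
                auc_oracle(a[bp], a[bn]) - auc_oracle(b[bp], b[bn])
            )
        var_boot = np.var(diffs, ddof=1)
        assert var_delong == pytest.approx(var_boot, rel=0.15)


class TestFisherExact:
    def test_published_specificity_comparison(self):
        assert round(fisher_exact(19, 19, 14, 19), 3) == 0.046

    def test_identical_proportions(self):
        assert fisher_exact(5, 10, 5, 10) == 1.0

    def test_enumeration_oracle(self):
        """Two-sided p equals the sum of hypergeometric probabilities not
        exceeding the observed table's, by full enumeration at fixed
        margins."""
        for (k1, n1, k2, n2) in [(19, 19, 14, 19), (3, 10, 7, 12), (0, 8, 5, 9)]:
            successes = k1 + k2
            p_obs = stats.hypergeom.pmf(k1, n1 + n2, successes, n1)
            p_sum = sum(
                stats.hypergeom.pmf(k, n1 + n2, successes, n1)
                for k in range(max(0, successes - n2), min(n1, successes) + 1)
                if stats.hypergeom.pmf(k, n1 + n2, successes, n1) <= p_obs * (1 + 1e-9)
            )
            assert fisher_exact(k1, n1, k2, n2) == pytest.approx(p_sum, rel=1e-9)

    def test_symmetry_under_group_and_outcome_swaps(self):
        p = fisher_exact(12, 20, 5, 15)
        assert fisher_exact(5, 15, 12, 20) == pytest.approx(p)
        assert fisher_exact(8, 20, 10, 15) == pytest.approx(p)


class TestGroupCompare:
    def test_identical_groups_mann_whitney(self):
        s, p = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], method="mann_whitney")
        assert p == 1.0

    def test_t_statistic_antisymmetry(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(1, 1, 12)
        s1, p1 = group_compare(x, y, method="t_test")
        s2, p2 = group_compare(y, x, method="t_test")
        assert s1 == pytest.approx(-s2)
        assert p1 == pytest.approx(p2)

    def test_mann_whitney_exact_matches_enumeration(self, rng):
        """For n₁=n₂=5 without ties, the exact two-sided p equals the
        fraction of all C(10,5) group assignments with U at least as
        extreme."""
        x = rng.normal(0, 1, 5)
        y = rng.normal(0.5, 1, 5)
        _, p = group_compare(x, y, method="mann_whitney")
        combined = np.concatenate([x, y])
        u_obs = sum(1 for a in x for b in y if a > b)
        n = 5
        us = []
        for idx in itertools.combinations(range(10), n):
            g1 = combined[list(idx)]
            g2 = np.delete(combined, list(idx))
            us.append(sum(1 for a in g1 for b in g2 if a > b))
        us = np.asarray(us)
        center = n * n / 2
        p_enum = np.mean(np.abs(us - center) >= abs(u_obs - center) - 1e-12)
        assert p == pytest.approx(p_enum, rel=1e-9)


class TestRaterAgreement:
    def test_perfect_agreement(self):
        r = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rep = rater_agreement(r, r.copy())
        assert rep.icc == pytest.approx(1.0)
        assert rep.cov_percent == 0.0

    def test_noise_attenuates_icc(self, rng):
        r1 = rng.normal(5, 1, 50)
        r2 = r1 + rng.normal(0, 3, 50)  # noise SD 3× the signal SD
        assert rater_agreement(r1, r2).icc < 0.5

    def test_matches_anova_decomposition(self, rng):
        """ICC(2,1) from the two-way ANOVA mean squares:
        (MSR − MSE) / (MSR + MSE + 2(MSC − MSE)/n)."""
        r1 = rng.normal(10, 2, 25)
        r2 = r1 + rng.normal(0.5, 1.0, 25)
        n = r1.size
        data = np.column_stack([r1, r2])
        grand = data.mean()
        row_means = data.mean(axis=1)
        col_means = data.mean(axis=0)
        msr = 2 * np.sum((row_means - grand) ** 2) / (n - 1)
        msc = n * np.sum((col_means - grand) ** 2) / (2 - 1)
        sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
        mse = sse / ((n - 1) * (2 - 1))
        icc_anova = (msr - mse) / (msr + mse + 2 * (msc - mse) / n)
        assert rater_agreement(r1, r2).icc == pytest.approx(icc_anova, abs=1e-9)


class TestStepwiseLogistic:
    def test_informative_variable_selected(self, rng):
        hits = 0
        for _ in range(100):
            n = 200
            y = np.array(["recurrence"] * (n // 2) + ["radionecrosis"] * (n // 2))
            informative = (y == "recurrence") * 1.5 + rng.normal(0, 1, n)
            noise = rng.normal(0, 1, n)
            res = stepwise_logistic(
                {"informative": informative, "noise": noise}, y, ["informative", "noise"]
            )
            if res.selected == ["informative"]:
                hits += 1
        assert hits >= 95

    def test_zero_candidates_rejected(self):
        with pytest.raises(ValidationError):
            stepwise_logistic({}, ["recurrence", "radionecrosis"], [])

    def test_null_type_one_control(self):
        rng = np.random.default_rng(12345)
        empty = 0
        for _ in range(100):
            n = 200
            y = np.array(["recurrence"] * (n // 2) + ["radionecrosis"] * (n // 2))
            x1 = rng.normal(0, 1, n)
            x2 = rng.normal(0, 1, n)
            res = stepwise_logistic({"x1": x1, "x2": x2}, y, ["x1", "x2"])
            if res.selected == []:
                empty += 1
        assert empty >= 90

    def test_perfect_separation_flagged(self):
        y = np.array(["recurrence"] * 10 + ["radionecrosis"] * 10)
        x = np.r_[np.ones(10), np.zeros(10)] + np.linspace(0, 0.1, 20)
        model = StepwiseLogisticRegression()
        with pytest.warns(UserWarning, match="separation"):
            model.fit(x[:, None], y, feature_names=["x"])
        assert model.separation_


def _loocv_cohort(ncbv90, pro, groups):
    records = [
        PatientRecord(
            f"p{i}",
            g,
            features=LesionFeatures(1.0, 0.75 * c, c, c, c, p),
        )
        for i, (c, p, g) in enumerate(zip(ncbv90, pro, groups))
    ]
    return CohortTable(records)


class TestLOOCV:
    def test_perfectly_separated_cohort(self):
        ncbv = [5, 6, 7, 8, 9, 10] + [1.0, 1.2, 1.4, 1.6, 1.8]
        pro = [1, 2, 3, 4, 5, 6] + [50, 60, 70, 80, 90]
        groups = ["recurrence"] * 6 + ["radionecrosis"] * 5
        assert loocv_accuracy(_loocv_cohort(ncbv, pro, groups)) == 100.0

    def test_shuffled_labels_near_majority_rate(self, rng):
        n = 30
        accs = []
        for _ in range(20):
            ncbv = rng.uniform(0, 10, n)
            pro = rng.uniform(0, 100, n)
            groups = rng.permutation(["recurrence"] * 18 + ["radionecrosis"] * 12)
            accs.append(loocv_accuracy(_loocv_cohort(ncbv, pro, groups)))
        majority = 100 * 18 / 30
        assert abs(np.mean(accs) - majority) <= 20

    def test_invariant_to_subject_ordering(self, rng):
        n = 16
        ncbv = rng.uniform(0, 10, n)
        pro = rng.uniform(0, 100, n)
        groups = np.array(["recurrence"] * 9 + ["radionecrosis"] * 7)
        a = loocv_accuracy(_loocv_cohort(ncbv, pro, groups))
        order = rng.permutation(n)
        b = loocv_accuracy(_loocv_cohort(ncbv[order], pro[order], groups[order]))
        assert a == b
        assert a <= 100.0

    def test_fixed_rule_variant(self):
        ncbv = [5, 6, 7, 8, 9, 10] + [1.0, 1.2, 1.4, 1.6, 1.8]
        pro = [1, 2, 3, 4, 5, 6] + [50, 60, 70, 80, 90]
        groups = ["recurrence"] * 6 + ["radionecrosis"] * 5
        cohort = _loocv_cohort(ncbv, pro, groups)
        assert loocv_accuracy(cohort, refit_cutoffs=False, rule=PAPER_RULE) == 100.0


class TestYoudenEstimator:
    def test_sklearn_protocol(self, rng):
        from sklearn.base import clone

        X = np.r_[rng.normal(2, 1, 20), rng.normal(0, 1, 20)][:, None]
        y = np.array(["recurrence"] * 20 + ["radionecrosis"] * 20)
        clf = YoudenThresholdClassifier(direction=GREATER)
        clone(clf).fit(X, y)
        clf.fit(X, y)
        assert hasattr(clf, "cutoff_")
        assert set(clf.predict(X)) <= {"recurrence", "radionecrosis"}
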