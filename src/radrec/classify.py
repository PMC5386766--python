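"""ROC analysis, cutoff selection, the two-parameter conjunction rule, and
the supporting statistics for differentiating recurrence from radionecrosis.

Recurrence is the positive class throughout.  nCBV90 discriminates in the
"greater is positive" direction (recurrent tumor is hyperperfused);
proSWMRI in the "lesser is positive" direction (radionecrosis is
hemorrhage-rich).  The combined rule predicts recurrence only when both
agree: nCBV90 > c1 AND proSWMRI ≤ c2, which trades sensitivity for the
elimination of false positives caused by hemorrhagic radionecrosis with
high perfusion signal.

The classifiers follow the scikit-learn estimator protocol (``fit`` /
``predict`` / ``get_params``) so they compose with pipelines and model
selection; the module-level functions are thin wrappers over the same
machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted

from .types import CohortTable, LesionFeatures, POSITIVE_CLASS, ValidationError

GREATER = "greater_is_positive"
LESSER = "lesser_is_positive"


# ---------------------------------------------------------------------------
# label handling


def _as_binary(labels, positive: Optional[str] = None):
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValidationError("both classes must be present")
    if classes.size > 2:
        raise ValidationError(f"expected binary labels; got {classes.size} classes")
    if positive is None:
        positive = POSITIVE_CLASS if POSITIVE_CLASS in classes else classes[-1]
    return (labels == positive).astype(int), positive


def _orient(scores: np.ndarray, direction: str) -> np.ndarray:
    if direction == GREATER:
        return scores
    if direction == LESSER:
        return -scores
    raise ValidationError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# ROC analysis and cutoff selection


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    auc_ci95: tuple
    direction: str
    scores: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)  # binary, 1 = positive


def roc_analysis(scores, labels, direction: str = GREATER, positive=None) -> ROCCurve:
    """Empirical ROC over all distinct score thresholds.

    Sensitivity/specificity are tabulated with the same boundary
    conventions the final rule uses (strict ``>`` for the greater
    direction, ``<=`` for the lesser direction).  AUC comes from the
    trapezoidal/Mann–Whitney identity; the 95% CI from the DeLong
    structural-component variance.
    """
    scores = np.asarray(scores, dtype=float)
    y, _ = _as_binary(labels, positive)
    if scores.shape[0] != y.shape[0]:
        raise ValidationError("scores and labels must have equal length")
    pos = np.sort(scores[y == 1])
    neg = np.sort(scores[y == 0])
    # candidate cutoffs at midpoints between adjacent distinct scores (plus
    # the two all-one-class extremes): Youden's J is identical to a scan of
    # observed values, but a midpoint cutoff leaves a symmetric margin on
    # both sides, which matters when the rule is applied to unseen subjects
    u = np.unique(scores)
    thresholds = np.concatenate([[-np.inf], (u[1:] + u[:-1]) / 2.0, [np.inf]])
    if direction == GREATER:
        # positive prediction iff score > t
        tp = pos.size - np.searchsorted(pos, thresholds, side="right")
        fp = neg.size - np.searchsorted(neg, thresholds, side="right")
    elif direction == LESSER:
        # positive prediction iff score <= t
        tp = np.searchsorted(pos, thresholds, side="right")
        fp = np.searchsorted(neg, thresholds, side="right")
    else:
        raise ValidationError(f"unknown direction {direction!r}")
    sens = tp / pos.size
    spec = 1.0 - fp / neg.size

    oriented = _orient(scores, direction)
    auc = float(roc_auc_score(y, oriented))
    var = _delong_covariance([oriented], y)[1][0, 0]
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    ci = (max(auc - half, 0.0), min(auc + half, 1.0))
    return ROCCurve(
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        auc_ci95=ci,
        direction=direction,
        scores=scores,
        y=y,
    )


class CutoffResult(NamedTuple):
    cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float
    degenerate: bool


def best_cutoff(roc: ROCCurve) -> CutoffResult:
    """Threshold maximizing Youden's J = sensitivity + specificity − 1.

    Ties are broken toward higher specificity (the combined rule's purpose
    is eliminating false positives), then toward the more conservative
    threshold.  All-equal scores give J = 0 everywhere and are flagged
    degenerate.
    """
    j = roc.sensitivities + roc.specificities - 1.0
    best_j = j.max()
    candidates = np.nonzero(j >= best_j - 1e-12)[0]
    specs = roc.specificities[candidates]
    candidates = candidates[specs >= specs.max() - 1e-12]
    idx = candidates[-1] if roc.direction == GREATER else candidates[0]
    degenerate = bool(best_j <= 1e-12)
    return CutoffResult(
        cutoff=float(roc.thresholds[idx]),
        youden_j=float(j[idx]),
        sensitivity=float(roc.sensitivities[idx]),
        specificity=float(roc.specificities[idx]),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# the conjunction rule


@dataclass
class ThresholdRule:
    """Predict recurrence iff nCBV90 > ncbv90_cutoff AND
    proSWMRI ≤ pro_swmri_cutoff."""

    ncbv90_cutoff: float
    pro_swmri_cutoff: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ncbv90_cutoff) or np.isinf(self.ncbv90_cutoff)):
            raise ValidationError("ncbv90_cutoff must not be NaN")
        if np.isnan(self.pro_swmri_cutoff):
            raise ValidationError("pro_swmri_cutoff must not be NaN")

    def decide(self, ncbv90, pro_swmri):
        ncbv90 = np.asarray(ncbv90, dtype=float)
        pro = np.asarray(pro_swmri, dtype=float)
        positive = (ncbv90 > self.ncbv90_cutoff) & (pro <= self.pro_swmri_cutoff)
        return np.where(positive, "recurrence", "radionecrosis")


#: the published operating point of the rule
PAPER_RULE = ThresholdRule(ncbv90_cutoff=2.07, pro_swmri_cutoff=15.76)


def apply_rule(features: LesionFeatures, rule: ThresholdRule) -> str:
    """Classify one patient's feature vector with the conjunction rule."""
    return str(rule.decide([features.ncbv90], [features.pro_swmri])[0])


@dataclass
class ClassifierReport:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fn + self.tn + self.fp
        return 100.0 * (self.tp + self.tn) / total


def confusion_metrics(predictions, labels, positive=None) -> ClassifierReport:
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValidationError("predictions and labels must have equal length")
    y, pos = _as_binary(labels, positive)
    p = (predictions == pos).astype(int)
    return ClassifierReport(
        tp=int(((p == 1) & (y == 1)).sum()),
        fn=int(((p == 0) & (y == 1)).sum()),
        tn=int(((p == 0) & (y == 0)).sum()),
        fp=int(((p == 1) & (y == 0)).sum()),
    )


# ---------------------------------------------------------------------------
# DeLong machinery


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    z = x[order]
    n = x.size
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and z[j] == z[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def _delong_covariance(oriented_scores: Sequence[np.ndarray], y: np.ndarray):
    """AUCs and their DeLong covariance for one or more paired score sets."""
    pos_idx = y == 1
    m = int(pos_idx.sum())
    n = int((~pos_idx).sum())
    k = len(oriented_scores)
    aucs = np.empty(k)
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    for r, s in enumerate(oriented_scores):
        s = np.asarray(s, dtype=float)
        px, nx = s[pos_idx], s[~pos_idx]
        tx = _midrank(np.concatenate([px, nx]))
        tp = _midrank(px)
        tn = _midrank(nx)
        aucs[r] = (tx[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v10[r] = (tx[:m] - tp) / n
        v01[r] = 1.0 - (tx[m:] - tn) / m
    s10 = np.atleast_2d(np.cov(v10, ddof=1)) if m > 1 else np.zeros((k, k))
    s01 = np.atleast_2d(np.cov(v01, ddof=1)) if n > 1 else np.zeros((k, k))
    return aucs, s10 / m + s01 / n


class DeLongResult(NamedTuple):
    auc_a: float
    auc_b: float
    p_value: float


def delong_compare(
    scores_a,
    scores_b,
    labels,
    direction_a: str = GREATER,
    direction_b: str = GREATER,
    positive=None,
) -> DeLongResult:
    """Paired DeLong test of the AUC difference between two score sets
    measured on the same subjects; two-sided p."""
    y, _ = _as_binary(labels, positive)
    a = _orient(np.asarray(scores_a, dtype=float), direction_a)
    b = _orient(np.asarray(scores_b, dtype=float), direction_b)
    if a.shape != b.shape or a.shape[0] != y.shape[0]:
        raise ValidationError("paired scores must match the labels in length")
    aucs, cov = _delong_covariance([a, b], y)
    diff = aucs[0] - aucs[1]
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var <= 1e-16:
        p = 1.0 if abs(diff) <= 1e-12 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return DeLongResult(auc_a=float(aucs[0]), auc_b=float(aucs[1]), p_value=p)


# ---------------------------------------------------------------------------
# classical tests


def fisher_exact(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher's exact p for k1/n1 successes vs k2/n2."""
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValidationError("require 0 <= k <= n in both groups")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def group_compare(x, y, method: str = "t_test"):
    """Two-sided two-sample comparison.

    ``t_test`` is the unpaired Student's t-test (equal variances).
    ``mann_whitney`` is exact for combined n ≤ 25 without ties, otherwise
    the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("empty group")
    if method == "t_test":
        if x.size < 2 or y.size < 2:
            raise ValidationError("t-test requires n >= 2 per group")
        res = stats.ttest_ind(x, y, equal_var=True)
        return float(res.statistic), float(res.pvalue)
    if method == "mann_whitney":
        combined = np.concatenate([x, y])
        no_ties = np.unique(combined).size == combined.size
        mw_method = "exact" if (combined.size <= 25 and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=mw_method)
        return float(res.statistic), float(res.pvalue)
    raise ValidationError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# inter-rater agreement


@dataclass
class AgreementReport:
    icc: float
    icc_ci95: tuple
    cov_percent: float


def rater_agreement(rater1, rater2) -> AgreementReport:
    """ICC(2,1) (two-way random effects, absolute agreement, single
    measures) with its F-based 95% CI, plus the within-subject coefficient
    of variation: mean over subjects of (pair SD / pair mean) × 100."""
    import pingouin as pg

    r1 = np.asarray(rater1, dtype=float)
    r2 = np.asarray(rater2, dtype=float)
    if r1.shape != r2.shape or r1.size < 3:
        raise ValidationError("paired measurements with n >= 3 required")
    n = r1.size
    long = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["a", "b"], n),
            "score": np.concatenate([r1, r2]),
        }
    )
    with warnings.catch_warnings():
        # degenerate (zero-residual) inputs trigger harmless divide warnings
        warnings.simplefilter("ignore", RuntimeWarning)
        icc_table = pg.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
    # single-measures absolute agreement, two-way random: ICC(2,1);
    # labelled ICC2 or ICC(A,1) depending on pingouin version
    key = "ICC2" if "ICC2" in icc_table.index else "ICC(A,1)"
    row = icc_table.loc[key]
    ci_col = "CI95%" if "CI95%" in icc_table.columns else "CI95"
    means = (r1 + r2) / 2.0
    sds = np.abs(r1 - r2) / np.sqrt(2.0)
    usable = means != 0
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} subject(s) with zero-mean pair excluded from CoV"
        )
    if not usable.any():
        raise ValidationError("no subject with nonzero pair mean for CoV")
    cov = float(100.0 * np.mean(sds[usable] / np.abs(means[usable])))
    return AgreementReport(
        icc=float(row["ICC"]), icc_ci95=tuple(row[ci_col]), cov_percent=cov
    )


# ---------------------------------------------------------------------------
# scikit-learn estimators


class YoudenThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Single-feature ROC classifier with the Youden-optimal cutoff.

    Parameters
    ----------
    direction : {'greater_is_positive', 'lesser_is_positive'}
        Which side of the cutoff predicts the positive class.
    """

    def __init__(self, direction: str = GREATER):
        self.direction = direction

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValidationError("expected a single feature column")
            X = X[:, 0]
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        _, self.positive_class_ = _as_binary(y)
        self.roc_ = roc_analysis(X, y, direction=self.direction)
        res = best_cutoff(self.roc_)
        self.cutoff_ = res.cutoff
        self.youden_j_ = res.youden_j
        self.degenerate_ = res.degenerate
        return self

    def decision_function(self, X):
        check_is_fitted(self, "cutoff_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return _orient(X, self.direction) - _orient(
            np.full_like(X, self.cutoff_), self.direction
        )

    def predict(self, X):
        check_is_fitted(self, "cutoff_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        if self.direction == GREATER:
            positive = X > self.cutoff_
        else:
            positive = X <= self.cutoff_
        negative = self.classes_[self.classes_ != self.positive_class_][0]
        return np.where(positive, self.positive_class_, negative)


class ConjunctionRuleClassifier(BaseEstimator, ClassifierMixin):
    """The two-parameter conjunction rule: recurrence iff nCBV90 > c1 AND
    proSWMRI ≤ c2.

    Columns of X are (nCBV90, proSWMRI).  Cutoffs left as ``None`` are
    derived at fit time as the per-feature Youden optima; fixed cutoffs
    (e.g. the published 2.07 / 15.76) may be supplied instead.
    """

    def __init__(self, ncbv90_cutoff: Optional[float] = None, pro_swmri_cutoff: Optional[float] = None):
        self.ncbv90_cutoff = ncbv90_cutoff
        self.pro_swmri_cutoff = pro_swmri_cutoff

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValidationError("X must have two columns: (ncbv90, pro_swmri)")
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        _, self.positive_class_ = _as_binary(y)
        c1 = self.ncbv90_cutoff
        c2 = self.pro_swmri_cutoff
        if c1 is None:
            c1 = best_cutoff(roc_analysis(X[:, 0], y, direction=GREATER)).cutoff
        if c2 is None:
            c2 = best_cutoff(roc_analysis(X[:, 1], y, direction=LESSER)).cutoff
        self.rule_ = ThresholdRule(ncbv90_cutoff=float(c1), pro_swmri_cutoff=float(c2))
        return self

    def predict(self, X):
        check_is_fitted(self, "rule_")
        X = np.asarray(X, dtype=float)
        return self.rule_.decide(X[:, 0], X[:, 1])


class StepwiseLogisticRegression(BaseEstimator, ClassifierMixin):
    """Stepwise logistic regression with likelihood-ratio selection.

    Forward entry requires LR-test p < ``entry_p``; backward removal drops
    the weakest retained variable when its LR p > ``removal_p``.  The
    fitted linear predictor serves as the combined score for ROC
    comparison.  Perfect separation is flagged via ``separation_``.
    """

    def __init__(self, entry_p: float = 0.05, removal_p: float = 0.10, max_iter: int = 50):
        self.entry_p = entry_p
        self.removal_p = removal_p
        self.max_iter = max_iter

    def fit(self, X, y, feature_names: Optional[Sequence[str]] = None):
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 1:
            raise ValidationError("at least one candidate variable required")
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(X.shape[1])]
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        yb, self.positive_class_ = _as_binary(y)

        selected: list[int] = []
        self.separation_ = False
        llf_cur, _, sep = self._loglik(X, yb, selected)
        self.separation_ |= sep
        for _ in range(self.max_iter):
            changed = False
            # forward entry
            best_p, best_var, best_llf = np.inf, None, None
            for v in range(X.shape[1]):
                if v in selected:
                    continue
                llf_new, _, sep = self._loglik(X, yb, selected + [v])
                self.separation_ |= sep
                lr = max(2.0 * (llf_new - llf_cur), 0.0)
                p = float(stats.chi2.sf(lr, df=1))
                if p < best_p:
                    best_p, best_var, best_llf = p, v, llf_new
            if best_var is not None and best_p < self.entry_p:
                selected.append(best_var)
                llf_cur = best_llf
                changed = True
            # backward removal
            worst_p, worst_var = -np.inf, None
            for v in selected:
                reduced = [u for u in selected if u != v]
                llf_red, _, sep = self._loglik(X, yb, reduced)
                self.separation_ |= sep
                lr = max(2.0 * (llf_cur - llf_red), 0.0)
                p = float(stats.chi2.sf(lr, df=1))
                if p > worst_p:
                    worst_p, worst_var = p, v
            if worst_var is not None and worst_p > self.removal_p:
                selected.remove(worst_var)
                llf_cur, _, sep = self._loglik(X, yb, selected)
                self.separation_ |= sep
                changed = True
            if not changed:
                break

        self.selected_ = [feature_names[v] for v in selected]
        self._selected_idx = selected
        llf, params, sep = self._loglik(X, yb, selected)
        self.separation_ |= sep
        if self.separation_:
            warnings.warn(
                "perfect or quasi-perfect separation detected; coefficients are unstable"
            )
        self.intercept_ = float(params[0])
        self.coef_ = dict(zip(self.selected_, (float(c) for c in params[1:])))
        self.llf_ = float(llf)
        self.scores_ = self._linear_predictor(X)
        return self

    def _loglik(self, X, yb, idx):
        import statsmodels.api as sm
        from statsmodels.tools.sm_exceptions import (
            ConvergenceWarning,
            PerfectSeparationWarning,
        )

        exog = sm.add_constant(X[:, idx] if idx else np.empty((X.shape[0], 0)), has_constant="add")
        separation = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                res = sm.Logit(yb, exog).fit(disp=0, maxiter=200)
            except Exception:
                res = sm.Logit(yb, exog).fit(method="bfgs", disp=0, maxiter=500)
            for w in caught:
                if issubclass(w.category, (PerfectSeparationWarning, ConvergenceWarning)):
                    separation = True
        return float(res.llf), np.asarray(res.params, dtype=float), separation

    def _linear_predictor(self, X):
        X = np.asarray(X, dtype=float)
        lp = np.full(X.shape[0], self.intercept_)
        for pos, idx in enumerate(self._selected_idx):
            lp += list(self.coef_.values())[pos] * X[:, idx]
        return lp

    def decision_function(self, X):
        check_is_fitted(self, "selected_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        return self._linear_predictor(X)

    def predict(self, X):
        lp = self.decision_function(X)
        negative = self.classes_[self.classes_ != self.positive_class_][0]
        return np.where(lp > 0, self.positive_class_, negative)


class StepwiseResult(NamedTuple):
    selected: list
    coefficients: dict
    scores: np.ndarray
    separation: bool


def stepwise_logistic(features, labels, candidates: Sequence[str]) -> StepwiseResult:
    """Functional wrapper: forward/backward LR-test selection over the named
    candidate columns of a feature table."""
    if len(candidates) == 0:
        raise ValidationError("at least one candidate variable required")
    frame = pd.DataFrame(features)[list(candidates)]
    model = StepwiseLogisticRegression().fit(frame, labels)
    return StepwiseResult(
        selected=model.selected_,
        coefficients={"const": model.intercept_, **model.coef_},
        scores=model.scores_,
        separation=model.separation_,
    )


# ---------------------------------------------------------------------------
# leave-one-out cross-validation of the conjunction rule


def loocv_accuracy(
    cohort: CohortTable,
    refit_cutoffs: bool = True,
    rule: Optional[ThresholdRule] = None,
) -> float:
    """LOOCV accuracy (%) of the conjunction rule.

    By default both Youden cutoffs are re-derived on each n−1 training
    fold (the honest variant); with ``refit_cutoffs=False`` a fixed rule
    is applied to every held-out subject.  Training folds that collapse to
    one class are flagged and excluded from the tally.
    """
    X = cohort.feature_matrix(("ncbv90", "pro_swmri"))
    y = cohort.labels()
    n = len(cohort)
    if n < 10 or np.unique(y).size < 2:
        raise ValidationError("LOOCV requires n >= 10 with both classes present")
    if not refit_cutoffs and rule is None:
        raise ValidationError("fixed-cutoff LOOCV requires a rule")
    correct = 0
    counted = 0
    for i in range(n):
        mask = np.arange(n) != i
        if np.unique(y[mask]).size < 2:
            warnings.warn(f"fold {i}: single-class training set; excluded")
            continue
        if refit_cutoffs:
            clf = ConjunctionRuleClassifier().fit(X[mask], y[mask])
            fold_rule = clf.rule_
        else:
            fold_rule = rule
        pred = fold_rule.decide([X[i, 0]], [X[i, 1]])[0]
        counted += 1
        correct += int(pred == y[i])
    if counted == 0:
        raise ValidationError("no valid LOOCV folds")
    return 100.0 * correct / counted
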