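"""Paired ROC statistics for diagnostic marker comparison.

This module is the statistical core of the pipeline: empirical AUC via the
Mann-Whitney statistic, DeLong's paired test for correlated AUCs
(structural-components / placement-value estimator), decision cutoffs at a
fixed training specificity with transfer to independent test cohorts,
McNemar's test on paired binary predictions, and the positive predictive
value under a population prevalence.

Scores are always oriented so that *higher means more case-like*; callers
that work with markers that decrease in disease should negate the marker
before passing it in (or rely on the orientation handling in
:mod:`mrmpanel.qc`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

__all__ = [
    "auc",
    "roc_curve",
    "delong_test",
    "DeLongResult",
    "sensitivity_at_specificity",
    "CutoffResult",
    "apply_cutoff",
    "mcnemar_test",
    "McNemarResult",
    "ppv",
]


# ---------------------------------------------------------------------------
# label handling


def as_case_indicator(labels) -> np.ndarray:
    """Coerce labels to a boolean case indicator.

    Accepts booleans, {0, 1} integers, or the strings ``"case"``/``"control"``.
    """
    y = np.asarray(labels)
    if y.dtype == bool:
        return y
    if y.dtype.kind in "iu" and set(np.unique(y)) <= {0, 1}:
        return y.astype(bool)
    if y.dtype.kind in "US":
        lowered = np.char.lower(y.astype(str))
        if set(np.unique(lowered)) <= {"case", "control"}:
            return lowered == "case"
    raise ValueError(
        "labels must be boolean, {0,1} or 'case'/'control'; got dtype "
        f"{y.dtype}"
    )


def _split_scores(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = as_case_indicator(labels)
    if s.shape != y.shape:
        raise ValueError(f"scores and labels differ in length: {s.shape} vs {y.shape}")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    cases, controls = s[y], s[~y]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both classes must be present")
    return cases, controls


# ---------------------------------------------------------------------------
# AUC


def auc(scores, labels) -> float:
    """Empirical AUC by the Mann-Whitney formulation, ties counted 1/2.

    Equals the trapezoidal area under the empirical ROC curve.
    """
    cases, controls = _split_scores(scores, labels)
    m, n = cases.size, controls.size
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * n))


def roc_curve(scores, labels):
    """(fpr, tpr) points of the empirical ROC curve, for plotting.

    Thresholds sweep the unique score values from high to low; the curve
    starts at (0, 0) and ends at (1, 1).
    """
    cases, controls = _split_scores(scores, labels)
    thresholds = np.unique(np.concatenate([cases, controls]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        tpr.append(float(np.mean(cases >= t)))
        fpr.append(float(np.mean(controls >= t)))
    return np.asarray(fpr), np.asarray(tpr)


# ---------------------------------------------------------------------------
# DeLong's paired AUC test


def _placements(cases: np.ndarray, controls: np.ndarray):
    """Mid-rank placement values (structural components).

    ``v10[i]`` is the fraction of controls scored below case ``i`` (ties 1/2);
    ``v01[j]`` is the fraction of cases scored above control ``j``.
    The mean of either vector is the AUC.
    """
    m, n = cases.size, controls.size
    combined = np.concatenate([cases, controls])
    r = stats.rankdata(combined)
    r_cases = stats.rankdata(cases)
    r_controls = stats.rankdata(controls)
    v10 = (r[:m] - r_cases) / n
    v01 = 1.0 - (r[m:] - r_controls) / m
    return v10, v01


@dataclass(frozen=True)
class DeLongResult:
    """Paired comparison of two AUCs on the same samples."""

    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    cov_ab: float
    z: float
    p_value: float
    degenerate: bool = False

    @property
    def auc_difference(self) -> float:
        return self.auc_a - self.auc_b


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """DeLong's test of equal AUC for two classifiers scored on one cohort.

    Uses the placement-value estimator of the paired AUC covariance matrix
    and a two-sided z-test on the AUC difference.  A zero estimated variance
    of the difference (e.g. identical score vectors) yields ``p = 1`` with
    ``degenerate=True``.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape:
        raise ValueError("score vectors must be on the same samples")
    y = as_case_indicator(labels)
    ca, qa = sa[y], sa[~y]
    cb, qb = sb[y], sb[~y]
    if ca.size == 0 or qa.size == 0:
        raise ValueError("both classes must be present")
    m, n = ca.size, qa.size

    v10a, v01a = _placements(ca, qa)
    v10b, v01b = _placements(cb, qb)
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())

    if m > 1:
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    else:
        s01 = np.zeros((2, 2))

    var_a = s10[0, 0] / m + s01[0, 0] / n
    var_b = s10[1, 1] / m + s01[1, 1] / n
    cov_ab = s10[0, 1] / m + s01[0, 1] / n
    var_diff = var_a + var_b - 2 * cov_ab

    if var_diff <= 0 or not math.isfinite(var_diff):
        return DeLongResult(auc_a, auc_b, var_a, var_b, cov_ab,
                            z=0.0, p_value=1.0, degenerate=True)
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return DeLongResult(auc_a, auc_b, var_a, var_b, cov_ab,
                        z=float(z), p_value=float(min(p, 1.0)))


# ---------------------------------------------------------------------------
# fixed-specificity cutoffs


@dataclass(frozen=True)
class CutoffResult:
    """A decision cutoff frozen on a training cohort."""

    cutoff: float
    specificity: float
    sensitivity: float


def sensitivity_at_specificity(scores, labels, spec_target: float) -> CutoffResult:
    """Smallest cutoff whose training specificity reaches ``spec_target``.

    Predictions are ``score >= cutoff`` (case-positive orientation), so the
    achieved specificity may strictly exceed the target when tied control
    values straddle the quantile.  The returned cutoff is meant to be frozen
    and transferred unchanged to independent test cohorts.
    """
    if not 0.0 < spec_target <= 1.0:
        raise ValueError(f"spec_target must be in (0, 1], got {spec_target}")
    cases, controls = _split_scores(scores, labels)
    all_scores = np.concatenate([cases, controls])
    candidates = np.unique(all_scores)
    # a cutoff just above the maximum score classifies everything negative
    candidates = np.append(candidates, np.nextafter(candidates[-1], np.inf))
    controls_sorted = np.sort(controls)
    n = controls.size
    for c in candidates:
        specificity = np.searchsorted(controls_sorted, c, side="left") / n
        if specificity >= spec_target:
            return CutoffResult(
                cutoff=float(c),
                specificity=float(specificity),
                sensitivity=float(np.mean(cases >= c)),
            )
    raise AssertionError("unreachable: the above-maximum cutoff has specificity 1")


def apply_cutoff(scores, labels, cutoff: float):
    """Apply a frozen cutoff: returns (sensitivity, specificity, predictions)."""
    s = np.asarray(scores, dtype=float)
    y = as_case_indicator(labels)
    pred = s >= cutoff
    sens = float(np.mean(pred[y])) if y.any() else float("nan")
    spec = float(np.mean(~pred[~y])) if (~y).any() else float("nan")
    return sens, spec, pred


# ---------------------------------------------------------------------------
# McNemar's test


@dataclass(frozen=True)
class McNemarResult:
    """Paired test on discordant prediction counts.

    ``b`` counts samples classifier A got right and B got wrong; ``c`` the
    reverse.  ``exact`` records whether the binomial or the chi-squared
    branch produced the p-value.
    """

    b: int
    c: int
    p_value: float
    exact: bool
    no_discordance: bool = False


def mcnemar_test(pred_a, pred_b, labels, scope: str = "cases",
                 exact_threshold: int = 25,
                 correction: bool = False) -> McNemarResult:
    """McNemar's two-sided test comparing two paired prediction vectors.

    ``scope="cases"`` restricts to case samples (a sensitivity comparison at
    matched specificity); ``scope="all"`` uses the whole cohort (diagnostic
    homogeneity).  The exact binomial p-value is used when ``b + c`` is below
    ``exact_threshold``, the asymptotic chi-squared test otherwise.  The
    chi-squared branch defaults to no continuity correction, which keeps the
    null rejection rate at its nominal level (the corrected statistic is
    conservative at the discordant-pair counts this pipeline sees).
    """
    pa = np.asarray(pred_a, dtype=bool)
    pb = np.asarray(pred_b, dtype=bool)
    y = as_case_indicator(labels)
    if pa.shape != pb.shape or pa.shape != y.shape:
        raise ValueError("prediction vectors and labels must have equal length")
    if scope == "cases":
        keep = y
    elif scope == "all":
        keep = np.ones_like(y, dtype=bool)
    else:
        raise ValueError(f"scope must be 'cases' or 'all', got {scope!r}")

    truth = y[keep]
    correct_a = pa[keep] == truth
    correct_b = pb[keep] == truth
    b = int(np.sum(correct_a & ~correct_b))
    c = int(np.sum(~correct_a & correct_b))
    if b + c == 0:
        return McNemarResult(b, c, p_value=1.0, exact=True, no_discordance=True)
    table = [[0, b], [c, 0]]
    use_exact = (b + c) < exact_threshold
    res = _sm_mcnemar(table, exact=use_exact, correction=correction)
    return McNemarResult(b, c, p_value=float(min(res.pvalue, 1.0)), exact=use_exact)


# ---------------------------------------------------------------------------
# predictive value


def ppv(sensitivity: float, specificity: float, prevalence: float) -> float:
    """Positive predictive value at a population prevalence.

    ``PPV = Se * P(D) / (Se * P(D) + (1 - Sp) * (1 - P(D)))``.

    A zero denominator (no positives possible) is defined as 0.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    num = sensitivity * prevalence
    den = num + (1.0 - specificity) * (1.0 - prevalence)
    if den == 0.0:
        return 0.0
    return num / den
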