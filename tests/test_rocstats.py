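"""Statistical core: AUC, DeLong, cutoff transfer, McNemar, PPV."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrmpanel import rocstats


# ---------------------------------------------------------------------------
# independent oracles


def auc_by_pair_counting(scores, labels):
    """Exhaustive Mann-Whitney pair counting (ties count 1/2)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    cases, controls = s[y], s[~y]
    total = 0.0
    for c in cases:
        for q in controls:
            total += 1.0 if c > q else (0.5 if c == q else 0.0)
    return total / (len(cases) * len(controls))


def naive_delong(sa, sb, labels):
    """Direct double-loop structural-components estimator."""
    sa, sb = np.asarray(sa, float), np.asarray(sb, float)
    y = np.asarray(labels, bool)

    def psi(x, yv):
        return 1.0 if x > yv else (0.5 if x == yv else 0.0)

    out = {}
    for name, s in (("a", sa), ("b", sb)):
        cases, controls = s[y], s[~y]
        m, n = len(cases), len(controls)
        v10 = np.array([np.mean([psi(c, q) for q in controls]) for c in cases])
        v01 = np.array([np.mean([psi(c, q) for c in cases]) for q in controls])
        out[name] = (v10, v01, v10.mean())
    v10a, v01a, auc_a = out["a"]
    v10b, v01b, auc_b = out["b"]
    m, n = len(v10a), len(v01a)

    def cov(u, v):
        return np.sum((u - u.mean()) * (v - v.mean())) / (len(u) - 1)

    var = (cov(v10a, v10a) + cov(v10b, v10b) - 2 * cov(v10a, v10b)) / m \
        + (cov(v01a, v01a) + cov(v01b, v01b) - 2 * cov(v01a, v01b)) / n
    z = (auc_a - auc_b) / math.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return auc_a, auc_b, var, z, p


def mcnemar_exact_by_pmf(b, c):
    """Two-sided exact binomial p by summing Binomial(b+c, 1/2) tails."""
    n = b + c
    k = min(b, c)
    pmf = [math.comb(n, i) * 0.5 ** n for i in range(n + 1)]
    return min(1.0, 2.0 * sum(pmf[: k + 1]))


# ---------------------------------------------------------------------------
# AUC


class TestAuc:
    @pytest.mark.parametrize("cases,controls,expected", [
        ([3, 4], [1, 2], 1.0),              # perfect separation
        ([1, 2], [1, 2], 0.5),              # full ties, half rule
        ([1, 3, 5], [2, 4], 3.0 / 6.0),     # pairs 3>2, 5>2, 5>4 of the 6
    ])
    def test_known_small_instances(self, cases, controls, expected):
        scores = np.array(cases + controls, float)
        labels = np.array([True] * len(cases) + [False] * len(controls))
        assert rocstats.auc(scores, labels) == pytest.approx(expected)

    def test_matches_pair_counting_on_random_instances(self, rng):
        """Tie-rich random instances with both classes up to n=8."""
        for _ in range(200):
            m = rng.integers(1, 9)
            n = rng.integers(1, 9)
            scores = rng.integers(0, 6, size=m + n).astype(float)
            labels = np.array([True] * m + [False] * n)
            assert rocstats.auc(scores, labels) == pytest.approx(
                auc_by_pair_counting(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rocstats.auc([1.0, 2.0], [True, True])

    @given(st.lists(st.floats(-100, 100), min_size=6, max_size=20, unique=True),
           st.integers(1, 5))
    @settings(max_examples=50, deadline=None)
    def test_complement_under_score_negation(self, values, n_case):
        """For tie-free scores, auc(s) + auc(-s) = 1."""
        scores = np.array(values)
        labels = np.zeros(len(scores), bool)
        labels[:n_case] = True
        a = rocstats.auc(scores, labels)
        assert a + rocstats.auc(-scores, labels) == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.standard_normal(40)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False
        a = rocstats.auc(scores, labels)
        assert rocstats.auc(np.exp(scores), labels) == pytest.approx(a)
        assert rocstats.auc(np.arctan(scores) * 3 + 7, labels) == pytest.approx(a)

    def test_roc_curve_endpoints_and_area(self, rng):
        scores = rng.standard_normal(60)
        labels = rng.random(60) < 0.4
        labels[0], labels[1] = True, False
        fpr, tpr = rocstats.roc_curve(scores, labels)
        assert fpr[0] == tpr[0] == 0.0 and fpr[-1] == tpr[-1] == 1.0
        assert np.trapezoid(tpr, fpr) == pytest.approx(
            rocstats.auc(scores, labels), abs=1e-12)


# ---------------------------------------------------------------------------
# DeLong


class TestDeLong:
    def test_identical_classifiers_are_degenerate(self, rng):
        s = rng.standard_normal(30)
        y = np.arange(30) < 12
        res = rocstats.delong_test(s, s, y)
        assert res.auc_difference == 0.0
        assert res.p_value == 1.0
        assert res.degenerate

    def test_matches_naive_double_loop(self, rng):
        """Placement-value implementation vs direct structural components."""
        for _ in range(25):
            n = int(rng.integers(6, 14))
            m = int(rng.integers(6, 14))
            y = np.array([True] * m + [False] * n)
            sa = rng.normal(y.astype(float), 1.0)
            sb = rng.normal(0.5 * y.astype(float), 1.0)
            res = rocstats.delong_test(sa, sb, y)
            auc_a, auc_b, var, z, p = naive_delong(sa, sb, y)
            assert res.auc_a == pytest.approx(auc_a, abs=1e-12)
            assert res.auc_b == pytest.approx(auc_b, abs=1e-12)
            var_impl = res.var_a + res.var_b - 2 * res.cov_ab
            assert var_impl == pytest.approx(var, abs=1e-12)
            assert res.z == pytest.approx(z, abs=1e-9)
            assert res.p_value == pytest.approx(p, abs=1e-9)

    def test_symmetry_negates_z(self, rng):
        y = np.array([True] * 20 + [False] * 25)
        sa = rng.normal(y * 1.0, 1.0)
        sb = rng.normal(y * 0.3, 1.0)
        r1 = rocstats.delong_test(sa, sb, y)
        r2 = rocstats.delong_test(sb, sa, y)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_consistent_with_paired_bootstrap(self, rng):
        """DeLong z/p agree with a paired bootstrap of the AUC difference."""
        n = 200
        y = np.arange(n) < 100
        signal = y.astype(float)
        sa = signal + rng.standard_normal(n)
        sb = signal + rng.standard_normal(n)
        res = rocstats.delong_test(sa, sb, y)

        boots = np.empty(10_000)
        ci = np.where(y)[0]
        qi = np.where(~y)[0]
        for b in range(10_000):
            idx = np.concatenate([rng.choice(ci, len(ci)), rng.choice(qi, len(qi))])
            yb = y[idx]
            boots[b] = rocstats.auc(sa[idx], yb) - rocstats.auc(sb[idx], yb)
        se_boot = boots.std(ddof=1)
        p_boot = 2 * stats.norm.sf(abs(res.auc_difference) / se_boot)
        assert abs(p_boot - res.p_value) < 0.05

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            rocstats.delong_test([1, 2, 3], [1, 2], [True, False, True])


# ---------------------------------------------------------------------------
# cutoffs


class TestCutoffs:
    def test_order_statistic_cutoff(self):
        scores = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12], float)
        labels = np.array([False] * 10 + [True] * 2)
        res = rocstats.sensitivity_at_specificity(scores, labels, 0.90)
        # smallest cutoff with >= 9 of 10 controls below it
        assert res.cutoff == 10.0
        assert res.specificity == pytest.approx(0.90)
        assert res.sensitivity == 1.0

    def test_target_one_puts_cutoff_above_control_maximum(self):
        scores = np.array([1, 2, 3, 10.0, 11.0])
        labels = np.array([False, False, False, True, True])
        res = rocstats.sensitivity_at_specificity(scores, labels, 1.0)
        assert res.cutoff > 3.0
        assert res.specificity == 1.0
        assert res.sensitivity == 1.0

    def test_ties_overshoot_matches_exhaustive_scan(self):
        """Tied controls straddling the quantile push specificity past the
        target; the chosen cutoff must agree with a scan of all thresholds."""
        controls = np.array([1, 2, 3, 4, 5, 9, 9, 9, 9, 9], float)
        cases = np.array([6.0, 10.0])
        scores = np.concatenate([controls, cases])
        labels = np.array([False] * 10 + [True] * 2)
        res = rocstats.sensitivity_at_specificity(scores, labels, 0.90)
        # exhaustive scan over candidate thresholds
        best = None
        for c in sorted(np.unique(scores)) + [np.nextafter(scores.max(), np.inf)]:
            spec = np.mean(controls < c)
            if spec >= 0.90:
                best = (c, spec)
                break
        assert res.cutoff == best[0]
        assert res.specificity == pytest.approx(best[1])
        assert res.specificity > 0.90  # strictly exceeds the target here

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            rocstats.sensitivity_at_specificity([1, 2], [True, False], 0.0)

    @pytest.mark.parametrize("cases,controls,cutoff,expected", [
        ([5, 6, 7], [1, 2], 4.0, (1.0, 1.0)),       # all cases above cutoff
        ([5, 6, 7], [1, 2], 100.0, (0.0, 1.0)),     # cutoff above everything
        ([1, 5, 6, 7], [1, 2, 3, 9], 4.0, (0.75, 0.75)),  # one miss each way
    ])
    def test_apply_cutoff_counting(self, cases, controls, cutoff, expected):
        scores = np.array(cases + controls, float)
        labels = np.array([True] * len(cases) + [False] * len(controls))
        sens, spec, pred = rocstats.apply_cutoff(scores, labels, cutoff)
        assert (sens, spec) == pytest.approx(expected)
        assert pred.tolist() == (scores >= cutoff).tolist()


# ---------------------------------------------------------------------------
# McNemar


class TestMcNemar:
    def test_identical_predictions_no_discordance(self):
        pred = np.array([True, False, True, False])
        y = np.array([True, True, False, False])
        res = rocstats.mcnemar_test(pred, pred, y, scope="all")
        assert res.b == res.c == 0
        assert res.p_value == 1.0
        assert res.no_discordance

    def test_one_sided_discordance_exact_tail(self):
        """b=10, c=0: exact two-sided p = 2 * 0.5^10."""
        y = np.ones(10, bool)
        pred_a = np.ones(10, bool)   # all correct
        pred_b = np.zeros(10, bool)  # all wrong
        res = rocstats.mcnemar_test(pred_a, pred_b, y, scope="cases")
        assert res.b == 10 and res.c == 0
        assert res.exact
        assert res.p_value == pytest.approx(2 * 0.5 ** 10)

    def test_exact_p_matches_binomial_pmf_sum(self):
        """b=15, c=5 stays on the exact branch (b+c < 25)."""
        y = np.ones(20, bool)
        pred_a = np.array([True] * 15 + [False] * 5)   # correct 15, wrong 5
        pred_b = np.array([False] * 15 + [True] * 5)   # wrong 15, correct 5
        res = rocstats.mcnemar_test(pred_a, pred_b, y, scope="cases")
        assert (res.b, res.c) == (15, 5)
        assert res.p_value == pytest.approx(mcnemar_exact_by_pmf(15, 5), abs=1e-12)

    def test_random_instances_match_pmf_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 24))
            y = np.ones(n, bool)
            pred_a = rng.random(n) < 0.7
            pred_b = rng.random(n) < 0.5
            res = rocstats.mcnemar_test(pred_a, pred_b, y, scope="cases")
            if res.b + res.c == 0:
                assert res.p_value == 1.0
            elif res.exact:
                assert res.p_value == pytest.approx(
                    mcnemar_exact_by_pmf(res.b, res.c), abs=1e-12)

    def test_scope_restricts_to_cases(self):
        y = np.array([True, True, False, False])
        pred_a = np.array([True, True, True, True])    # right on cases only
        pred_b = np.array([False, False, False, False])  # wrong on cases only
        cases_res = rocstats.mcnemar_test(pred_a, pred_b, y, scope="cases")
        all_res = rocstats.mcnemar_test(pred_a, pred_b, y, scope="all")
        assert (cases_res.b, cases_res.c) == (2, 0)
        assert (all_res.b, all_res.c) == (2, 2)
        with pytest.raises(ValueError):
            rocstats.mcnemar_test(pred_a, pred_b, y, scope="controls")


# ---------------------------------------------------------------------------
# PPV


class TestPpv:
    def test_perfect_test_has_unit_ppv(self):
        assert rocstats.ppv(1.0, 1.0, 0.3) == 1.0

    def test_uninformative_test_returns_prevalence_symmetry(self):
        assert rocstats.ppv(0.5, 0.5, 0.5) == pytest.approx(0.5)

    def test_reported_operating_point(self):
        """Sensitivity 0.825 / specificity 0.944 at prevalence 12.9e-5,
        checked against independent evaluation of the printed formula."""
        se, sp, p = 0.825, 0.944, 12.9e-5
        expected = (se * p) / (se * p + (1 - sp) * (1 - p))
        assert rocstats.ppv(se, sp, p) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0018971, abs=1e-6)

    def test_zero_denominator_defined_as_zero(self):
        assert rocstats.ppv(0.0, 1.0, 0.0) == 0.0

    def test_monotone_in_all_arguments(self):
        grid = np.linspace(0.05, 0.95, 7)
        for sp in grid:
            vals = [rocstats.ppv(se, sp, 1e-3) for se in grid]
            assert all(b >= a for a, b in zip(vals, vals[1:]))
        for se in grid:
            vals = [rocstats.ppv(se, sp, 1e-3) for sp in grid]
            assert all(b >= a for a, b in zip(vals, vals[1:]))
            vals = [rocstats.ppv(se, 0.9, p) for p in grid]
            assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rocstats.ppv(1.2, 0.5, 0.5)
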