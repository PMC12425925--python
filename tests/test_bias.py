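"""Egger/Begg bias tests and leave-out sensitivity analyses."""

import math

import numpy as np
import pytest
from scipy import stats

from fieldsynopsis.bias import assess_bias, begg_test, egger_test, sensitivity_exclude
from fieldsynopsis.effects import effect_from_study
from fieldsynopsis.records import EffectEstimate, InsufficientDataError


def _effects(pairs):
    return [EffectEstimate(study_id=f"s{i}", log_or=t, se=s)
            for i, (t, s) in enumerate(pairs)]


class TestEgger:
    def test_collinear_effects_zero_intercept(self):
        # identical true effect: points (1/se, c/se) lie on a line through 0
        pairs = [(0.4, s) for s in (0.1, 0.15, 0.2, 0.3, 0.4)]
        intercept, _, _ = egger_test(_effects(pairs))
        assert intercept == pytest.approx(0.0, abs=1e-10)

    def test_matches_closed_form_ols(self):
        # small studies inflated: positive intercept; oracle is textbook OLS
        pairs = [(0.1, 0.05), (0.12, 0.08), (0.15, 0.1), (0.6, 0.35), (0.8, 0.45)]
        effects = _effects(pairs)
        intercept, se_int, p = egger_test(effects)
        x = np.array([1 / s for _, s in pairs])
        y = np.array([t / s for t, s in pairs])
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma2 = resid @ resid / (len(x) - 2)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        assert intercept > 0
        assert intercept == pytest.approx(beta[0], abs=1e-9)
        assert se_int == pytest.approx(math.sqrt(cov[0, 0]), abs=1e-9)
        t_stat = beta[0] / math.sqrt(cov[0, 0])
        assert p == pytest.approx(2 * stats.t.sf(abs(t_stat), 3), abs=1e-12)

    def test_order_invariant(self):
        pairs = [(0.1, 0.05), (0.5, 0.2), (0.3, 0.1), (0.7, 0.4)]
        assert egger_test(_effects(pairs)) == pytest.approx(
            egger_test(_effects(pairs[::-1]))
        )

    def test_too_few_studies(self):
        with pytest.raises(InsufficientDataError):
            egger_test(_effects([(0.1, 0.1), (0.2, 0.2)]))


class TestBegg:
    def test_perfect_discordance_k5(self):
        # construct deviates decreasing while variances increase: tau = -1,
        # S = -10 over the C(5,2)=10 pairs, Var(S) = 5*4*15/18
        pairs = [(1.0, 0.1), (0.55, 0.2), (0.3, 0.3), (0.1, 0.4), (-0.4, 0.5)]
        effects = _effects(pairs)
        z, p = begg_test(effects)
        # brute-force S over all pairs of (deviate, variance)
        theta = np.array([t for t, _ in pairs])
        v = np.array([s**2 for _, s in pairs])
        w = 1 / v
        dev = (theta - (w * theta).sum() / w.sum()) / np.sqrt(v - 1 / w.sum())
        s_brute = sum(
            np.sign(dev[i] - dev[j]) * np.sign(v[i] - v[j])
            for i in range(5) for j in range(i + 1, 5)
        )
        assert s_brute == -10  # fully discordant by construction
        expected_z = -10 / math.sqrt(5 * 4 * 15 / 18)
        assert z == pytest.approx(expected_z, abs=1e-9)
        assert p == pytest.approx(2 * stats.norm.sf(abs(expected_z)), abs=1e-12)

    def test_matches_scipy_kendall_no_ties(self):
        rng = np.random.default_rng(3)
        pairs = list(zip(rng.normal(0.2, 0.5, 7), rng.uniform(0.05, 0.6, 7)))
        effects = _effects(pairs)
        z, p = begg_test(effects)
        theta = np.array([t for t, _ in pairs])
        v = np.array([s**2 for _, s in pairs])
        w = 1 / v
        dev = (theta - (w * theta).sum() / w.sum()) / np.sqrt(v - 1 / w.sum())
        tau = stats.kendalltau(dev, v, method="asymptotic")
        assert p == pytest.approx(tau.pvalue, rel=1e-6)

    def test_balanced_concordance_is_null(self):
        # deviate ranks chosen so concordant and discordant pairs cancel
        pairs = [(0.0, 0.1), (1.0, 0.2), (0.5, 0.3)]
        theta = np.array([t for t, _ in pairs])
        v = np.array([s**2 for _, s in pairs])
        w = 1 / v
        dev = (theta - (w * theta).sum() / w.sum()) / np.sqrt(v - 1 / w.sum())
        order = np.argsort(v)
        signs = np.sign(np.diff(dev[order]))
        assert signs[0] * signs[1] < 0  # middle deviate is extremal → S = ±1 ∓ 1 ...
        z, p = begg_test(_effects(pairs))
        # S sums to +1 -1 +... small; just check |z| small and p large
        assert p > 0.5

    def test_location_invariance(self):
        pairs = [(0.1, 0.1), (0.4, 0.2), (0.2, 0.3), (0.6, 0.4)]
        shifted = [(t + 2.5, s) for t, s in pairs]
        assert begg_test(_effects(pairs))[1] == pytest.approx(
            begg_test(_effects(shifted))[1], abs=1e-9
        )

    def test_too_few_studies(self):
        with pytest.raises(InsufficientDataError):
            begg_test(_effects([(0.1, 0.1), (0.2, 0.2)]))


class TestSensitivity:
    def _studies(self, make_study, specs):
        """specs: (year, or, lo, hi) per study."""
        return [
            make_study(study_id=f"s{i}", year=y, reported_or=o, ci_low=lo,
                       ci_high=hi, variant_id="rs9")
            for i, (y, o, lo, hi) in enumerate(specs)
        ]

    def test_robust_signal_retained(self, make_study):
        specs = [(2000 + i, 1.8, 1.4, 2.3) for i in range(5)]
        records = self._studies(make_study, specs)
        effects = [effect_from_study(r) for r in records]
        for rule in ("first_published", "first_positive"):
            repooled, retained = sensitivity_exclude(effects, records, rule)
            assert retained is True
            assert repooled.k == 4

    def test_signal_carried_by_earliest_study_lost(self, make_study):
        # only the 2000 study is individually significant; dropping it
        # leaves a null pool whose CI spans 1
        specs = [(2000, 3.5, 2.5, 4.9), (2005, 1.05, 0.8, 1.38),
                 (2007, 0.98, 0.75, 1.28), (2010, 1.02, 0.78, 1.33)]
        records = self._studies(make_study, specs)
        effects = [effect_from_study(r) for r in records]
        _, retained = sensitivity_exclude(effects, records, "first_positive")
        assert retained is False

    def test_first_published_vs_first_positive_differ(self, make_study):
        # earliest study is null; first positive comes later
        specs = [(1998, 1.02, 0.8, 1.31), (2001, 2.5, 1.8, 3.5),
                 (2004, 2.4, 1.7, 3.4), (2006, 2.3, 1.6, 3.3)]
        records = self._studies(make_study, specs)
        effects = [effect_from_study(r) for r in records]
        repooled_pub, _ = sensitivity_exclude(effects, records, "first_published")
        repooled_pos, _ = sensitivity_exclude(effects, records, "first_positive")
        assert repooled_pub.pooled_log_or > repooled_pos.pooled_log_or

    def test_no_positive_study_returns_unchanged(self, make_study):
        specs = [(2000, 1.1, 0.9, 1.35), (2002, 1.08, 0.88, 1.33),
                 (2004, 1.12, 0.9, 1.4)]
        records = self._studies(make_study, specs)
        effects = [effect_from_study(r) for r in records]
        repooled, retained = sensitivity_exclude(effects, records, "first_positive")
        assert retained is True
        assert repooled.k == 3  # nothing excluded

    def test_exclusion_changes_k_by_one(self, make_study):
        specs = [(2000, 1.8, 1.3, 2.5), (2003, 1.7, 1.2, 2.4), (2005, 1.6, 1.1, 2.3)]
        records = self._studies(make_study, specs)
        effects = [effect_from_study(r) for r in records]
        repooled, _ = sensitivity_exclude(effects, records, "first_published")
        assert repooled.k == len(effects) - 1


class TestAssessBias:
    def test_flags_follow_thresholds(self, make_study):
        specs = [(2000, 1.8, 1.4, 2.3), (2001, 1.7, 1.2, 2.4),
                 (2002, 1.9, 1.5, 2.4), (2003, 1.75, 1.3, 2.35),
                 (2004, 1.85, 1.35, 2.5)]
        records = [
            make_study(study_id=f"s{i}", year=y, reported_or=o, ci_low=lo, ci_high=hi)
            for i, (y, o, lo, hi) in enumerate(specs)
        ]
        effects = [effect_from_study(r) for r in records]
        assessment = assess_bias(effects, records)
        assert assessment.computable
        assert assessment.publication_bias == (assessment.begg_p < 0.10)
        assert assessment.small_study_bias == (assessment.egger_p < 0.10)
        assert assessment.flags == frozenset()

    def test_not_computable_below_three_studies(self, make_study):
        records = [make_study(study_id=f"s{i}") for i in range(2)]
        effects = [effect_from_study(r) for r in records]
        assessment = assess_bias(effects, records)
        assert not assessment.computable
        assert assessment.egger_p is None and assessment.begg_p is None
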