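"""Pooling engine: fixed/random effects, heterogeneity, subgroups, regression."""

import math

import numpy as np
import pytest
from statsmodels.stats.meta_analysis import combine_effects

from fieldsynopsis.effects import se_from_ci
from fieldsynopsis.meta import (
    cochran_q,
    i_squared,
    meta_analyze,
    meta_regression,
    pool_fixed,
    pool_random_dl,
    select_model,
    subgroup_analysis,
)
from fieldsynopsis.records import EffectEstimate, EligibilityError, InsufficientDataError


def _effects(pairs):
    return [EffectEstimate(study_id=f"s{i}", log_or=t, se=s)
            for i, (t, s) in enumerate(pairs)]


class TestPoolFixed:
    def test_single_study_identity(self):
        res = pool_fixed(_effects([(0.3, 0.1)]))
        assert (res.pooled_log_or, res.pooled_se) == (0.3, 0.1)

    def test_equal_weights_average(self):
        res = pool_fixed(_effects([(0.2, 0.1), (0.4, 0.1)]))
        assert res.pooled_log_or == pytest.approx(0.3, abs=1e-12)
        assert res.pooled_se == pytest.approx(0.1 / math.sqrt(2), abs=1e-12)

    def test_weighted_mean_three_studies(self):
        # brute-force oracle: w = 25, 100, 11.11..; Σwθ/Σw
        res = pool_fixed(_effects([(0.1, 0.2), (0.5, 0.1), (0.3, 0.3)]))
        w = np.array([25.0, 100.0, 1 / 0.09])
        t = np.array([0.1, 0.5, 0.3])
        assert res.pooled_log_or == pytest.approx(float((w * t).sum() / w.sum()), abs=1e-12)
        assert res.pooled_log_or == pytest.approx(0.410204, abs=5e-7)
        assert res.pooled_se == pytest.approx(0.085714, abs=5e-7)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool_fixed([])

    def test_against_statsmodels(self):
        rng = np.random.default_rng(7)
        theta = rng.normal(0.2, 0.3, size=8)
        se = rng.uniform(0.05, 0.4, size=8)
        res = pool_fixed(_effects(list(zip(theta, se))))
        sm = combine_effects(theta, se**2, method_re="dl")
        assert res.pooled_log_or == pytest.approx(sm.mean_effect_fe, rel=1e-10)
        assert res.q_stat == pytest.approx(sm.q, rel=1e-10)


class TestCochranQ:
    def test_identical_effects_give_zero(self):
        q, df, p = cochran_q(_effects([(0.2, 0.1), (0.2, 0.3), (0.2, 0.2)]))
        assert q == pytest.approx(0.0, abs=1e-12)
        assert (df, p) == (2, pytest.approx(1.0))

    def test_two_study_direct_substitution(self):
        q, df, _ = cochran_q(_effects([(0.0, 0.1), (0.2, 0.1)]))
        assert q == pytest.approx(2.0, abs=1e-12)
        assert df == 1

    def test_permutation_invariant(self):
        pairs = [(0.1, 0.2), (0.5, 0.1), (0.3, 0.3), (-0.2, 0.15)]
        q1, *_ = cochran_q(_effects(pairs))
        q2, *_ = cochran_q(_effects(pairs[::-1]))
        assert q1 == pytest.approx(q2, rel=1e-12)

    def test_single_study_undefined(self):
        with pytest.raises(ValueError):
            cochran_q(_effects([(0.1, 0.1)]))


class TestISquared:
    @pytest.mark.parametrize(
        "q, df, expected", [(0.0, 2, 0.0), (4.0, 2, 50.0), (1.0, 2, 0.0), (10.0, 1, 90.0)]
    )
    def test_values(self, q, df, expected):
        assert i_squared(q, df) == pytest.approx(expected)


class TestPoolRandomDL:
    def test_homogeneous_reduces_to_fixed(self):
        pairs = [(0.2, 0.1), (0.2, 0.2), (0.2, 0.15)]
        re = pool_random_dl(_effects(pairs))
        fe = pool_fixed(_effects(pairs))
        assert re.tau_squared == 0.0
        assert re.pooled_log_or == pytest.approx(fe.pooled_log_or, abs=1e-12)
        assert re.pooled_se == pytest.approx(fe.pooled_se, abs=1e-12)

    def test_moment_estimator_direct_substitution(self):
        res = pool_random_dl(_effects([(0.0, 0.1), (1.0, 0.1)]))
        # Q = 50, df = 1, Σw = 200, Σw²/Σw = 100 → τ² = 49/100
        assert res.tau_squared == pytest.approx(0.49, abs=1e-12)
        assert res.pooled_log_or == pytest.approx(0.5, abs=1e-12)

    def test_random_se_never_below_fixed(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 10))
            pairs = list(zip(rng.normal(0, 0.5, k), rng.uniform(0.05, 0.5, k)))
            re = pool_random_dl(_effects(pairs))
            fe = pool_fixed(_effects(pairs))
            assert re.pooled_se >= fe.pooled_se - 1e-12

    def test_against_statsmodels_dl(self):
        rng = np.random.default_rng(11)
        theta = rng.normal(0.3, 0.4, size=10)
        se = rng.uniform(0.05, 0.4, size=10)
        res = pool_random_dl(_effects(list(zip(theta, se))))
        sm = combine_effects(theta, se**2, method_re="dl")
        assert res.tau_squared == pytest.approx(sm.tau2, rel=1e-10)
        assert res.pooled_log_or == pytest.approx(sm.mean_effect_re, rel=1e-10)


class TestModelSwitch:
    @pytest.mark.parametrize(
        "i2, expected",
        [(55.6, "random"), (12.7, "fixed"), (50.0, "random"), (49.99, "fixed"),
         (0.0, "fixed"), (100.0, "random")],
    )
    def test_boundary_inclusive(self, i2, expected):
        assert select_model(i2) == expected


class TestMetaAnalyze:
    def test_eligibility_floor(self):
        with pytest.raises(EligibilityError):
            meta_analyze(_effects([(0.1, 0.1), (0.2, 0.1)]))

    def test_floor_overridable_for_sensitivity(self):
        res = meta_analyze(_effects([(0.1, 0.1), (0.2, 0.1)]), min_k=2)
        assert res.k == 2

    def test_homogeneous_triple_uses_fixed(self):
        res = meta_analyze(_effects([(0.2, 0.1), (0.25, 0.12), (0.22, 0.15)]))
        assert res.model == "fixed"
        assert res.tau_squared == 0.0

    def test_heterogeneous_triple_switches_to_random(self):
        res = meta_analyze(_effects([(0.0, 0.05), (0.8, 0.05), (0.4, 0.05)]))
        assert res.i_squared >= 50.0
        assert res.model == "random"
        assert res.tau_squared > 0.0

    def test_ci_brackets_pooled_or(self):
        res = meta_analyze(_effects([(0.2, 0.1), (0.3, 0.2), (0.4, 0.3)]))
        assert res.ci_low < math.exp(res.pooled_log_or) < res.ci_high


class TestSubgroupAnalysis:
    def test_identical_subgroups_no_interaction(self):
        pairs = [(0.3, 0.1), (0.3, 0.1), (0.3, 0.1), (0.3, 0.1)]
        res = subgroup_analysis(_effects(pairs), ["A", "A", "B", "B"])
        assert res.q_between == pytest.approx(0.0, abs=1e-12)
        assert res.p_interaction == pytest.approx(1.0)
        assert res.df_between == 1

    def test_published_ethnic_heterogeneity_flag(self):
        # Asian pool OR 1.58 (1.32, 1.90) vs Caucasian pool OR 3.52 (2.38, 5.19)
        # printed interaction P is "<0.001"
        w_a = se_from_ci(1.32, 1.90) ** -2
        w_c = se_from_ci(2.38, 5.19) ** -2
        t_a, t_c = math.log(1.58), math.log(3.52)
        grand = (w_a * t_a + w_c * t_c) / (w_a + w_c)
        q_oracle = w_a * (t_a - grand) ** 2 + w_c * (t_c - grand) ** 2
        assert q_oracle == pytest.approx(13.3, abs=0.1)
        assert q_oracle > 10.828  # chi2(1) critical value at 0.001

    def test_order_invariance(self):
        pairs = [(0.1, 0.1), (0.2, 0.1), (0.6, 0.1), (0.7, 0.1)]
        labels = ["A", "A", "B", "B"]
        r1 = subgroup_analysis(_effects(pairs), labels)
        r2 = subgroup_analysis(_effects(pairs[::-1]), labels[::-1])
        assert r1.q_between == pytest.approx(r2.q_between, rel=1e-12)

    def test_small_groups_dropped_and_eligibility(self):
        pairs = [(0.1, 0.1), (0.2, 0.1), (0.3, 0.1)]
        with pytest.raises(EligibilityError):
            subgroup_analysis(_effects(pairs), ["A", "A", "B"])

    def test_q_decomposition_under_fixed_weights(self, rng):
        # Q_total = Σ Q_within + Q_between when FE weights are used throughout
        k = 12
        pairs = list(zip(rng.normal(0.2, 0.4, k), rng.uniform(0.05, 0.4, k)))
        labels = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        effects = _effects(pairs)
        q_total, _, _ = cochran_q(effects)
        res = subgroup_analysis(effects, labels, model="fixed")
        q_within = sum(r.q_stat for r in res.per_subgroup.values())
        assert q_within + res.q_between == pytest.approx(q_total, abs=1e-9)


class TestMetaRegression:
    def test_noiseless_linear_recovery(self):
        x = [0.0, 1.0, 2.0, 3.0, 4.0]
        effects = _effects([(0.1 + 0.25 * xi, 1e-4) for xi in x])
        res = meta_regression(effects, x)
        assert res.coefficient == pytest.approx(0.25, abs=1e-6)
        assert res.tau_squared_residual == pytest.approx(0.0, abs=1e-8)

    def test_constant_covariate_rejected(self):
        effects = _effects([(0.1, 0.1)] * 5)
        with pytest.raises(ValueError, match="constant"):
            meta_regression(effects, [1.0] * 5)

    def test_minimum_studies(self):
        with pytest.raises(InsufficientDataError):
            meta_regression(_effects([(0.1, 0.1)] * 3), [0, 1, 2])

    def test_null_covariate_slope_near_zero(self, rng):
        # covariate unrelated to effects: slope ≈ 0 within Monte-Carlo error
        slopes = []
        for _ in range(200):
            k = 20
            theta = rng.normal(0.3, 0.1, k)
            se = rng.uniform(0.08, 0.3, k)
            theta = theta + rng.normal(0, se)
            x = rng.normal(0, 1, k)
            effects = _effects(list(zip(theta, se)))
            slopes.append(meta_regression(effects, x).coefficient)
        mean_slope = float(np.mean(slopes))
        mc_sd = float(np.std(slopes) / math.sqrt(len(slopes)))
        assert abs(mean_slope) < 4 * mc_sd + 1e-3

    def test_binary_covariate_matches_subgroup_direction(self, rng):
        # a binary moderator duplicating a subgroup split must agree in
        # direction of significance with the between-subgroup Q test
        pairs = [(0.1, 0.08), (0.15, 0.09), (0.12, 0.1),
                 (0.8, 0.08), (0.85, 0.09), (0.9, 0.1)]
        labels = ["A"] * 3 + ["B"] * 3
        x = [0.0] * 3 + [1.0] * 3
        effects = _effects(pairs)
        reg = meta_regression(effects, x)
        sub = subgroup_analysis(effects, labels)
        assert (reg.p_value < 0.05) == (sub.p_interaction < 0.05) == True  # noqa: E712
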