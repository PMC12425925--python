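"""Publication-bias and small-study tests plus leave-one-out sensitivity.

Egger's test regresses the standardized effect θᵢ/seᵢ on precision
1/seᵢ; a non-zero intercept signals small-study effects.  Begg's test
rank-correlates variance-standardized deviates with study variances
(Kendall's S with tie-corrected normal approximation).  Sensitivity
analysis re-pools after dropping the first published, or first positive,
study and asks whether significance survives.  All three feed the
"protection from bias" Venice letter; P < 0.10 is the flag threshold.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .meta import meta_analyze, pool_fixed
from .records import (
    BiasAssessment,
    EffectEstimate,
    InsufficientDataError,
    MetaResult,
    StudyRecord,
)

__all__ = ["egger_test", "begg_test", "sensitivity_exclude", "assess_bias"]


def egger_test(effects: Sequence[EffectEstimate]) -> tuple[float, float, float]:
    """Egger regression intercept, its SE, and the two-sided t-test P (k-2 df)."""
    k = len(effects)
    if k < 3:
        raise InsufficientDataError("Egger's test requires at least three studies")
    theta = np.array([e.log_or for e in effects])
    se = np.array([e.se for e in effects])
    y = theta / se  # standardized effect
    x = 1.0 / se  # precision
    if np.ptp(x) == 0:
        raise InsufficientDataError(
            "Egger's test needs variation in study precision (all se equal)"
        )
    fit = stats.linregress(x, y)
    intercept = float(fit.intercept)
    intercept_se = float(fit.intercept_stderr)
    if intercept_se == 0.0:
        return intercept, 0.0, 1.0 if intercept == 0.0 else 0.0
    t = intercept / intercept_se
    p = float(2.0 * stats.t.sf(abs(t), k - 2))
    return intercept, intercept_se, p


def begg_test(effects: Sequence[EffectEstimate]) -> tuple[float, float]:
    """Begg–Mazumdar rank correlation test: normalized Kendall z and P.

    Deviates are (θᵢ − θ̂_FE)/sqrt(vᵢ − v̄) with v̄ the variance of the
    fixed-effects pool; these are rank-correlated with the vᵢ.  The S
    statistic (concordant minus discordant pairs) is referred to a
    normal with the tie-corrected Kendall variance; no continuity
    correction is applied.
    """
    k = len(effects)
    if k < 3:
        raise InsufficientDataError("Begg's test requires at least three studies")
    theta = np.array([e.log_or for e in effects])
    v = np.array([e.se**2 for e in effects])
    w = 1.0 / v
    theta_fe = np.sum(w * theta) / np.sum(w)
    v_pool = 1.0 / np.sum(w)
    denom = np.sqrt(np.maximum(v - v_pool, 1e-300))
    deviates = (theta - theta_fe) / denom

    s = 0
    for i in range(k):
        for j in range(i + 1, k):
            s += int(np.sign(deviates[i] - deviates[j]) * np.sign(v[i] - v[j]))

    def _tie_sizes(values: np.ndarray) -> list[int]:
        _, counts = np.unique(values, return_counts=True)
        return [int(c) for c in counts if c > 1]

    def _t0(ties: list[int]) -> float:
        return sum(t * (t - 1) * (2 * t + 5) for t in ties)

    n0 = k * (k - 1) * (2 * k + 5)
    var_s = (n0 - _t0(_tie_sizes(deviates)) - _t0(_tie_sizes(v))) / 18.0
    if var_s <= 0:
        return 0.0, 1.0
    z = s / math.sqrt(var_s)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), p


def _is_positive(record: StudyRecord, effect: EffectEstimate, direction: float) -> bool:
    """Study is 'positive' when its own 95% CI excludes OR=1 in the pooled direction."""
    z = effect.log_or / effect.se
    if abs(z) < 1.959964:
        return False
    return math.copysign(1.0, effect.log_or) == math.copysign(1.0, direction)


def sensitivity_exclude(
    effects: Sequence[EffectEstimate],
    records: Sequence[StudyRecord],
    rule: str = "first_published",
) -> tuple[MetaResult, bool]:
    """Re-pool after excluding one study per the sensitivity rule.

    ``first_published``: smallest publication year, ties broken by first
    author then study id.  ``first_positive``: earliest-published study
    whose own CI excludes 1 in the direction of the pooled estimate; if
    no study qualifies the original pool is returned with a retained
    flag of True.  ``retained`` reports whether the re-pooled 95% CI
    still excludes OR = 1.
    """
    if rule not in ("first_published", "first_positive"):
        raise ValueError(f"unknown sensitivity rule {rule!r}")
    if len(effects) != len(records):
        raise ValueError("records must align one-to-one with effects")
    if len(effects) < 3:
        raise InsufficientDataError("sensitivity exclusion requires at least three studies")

    order = sorted(
        range(len(records)),
        key=lambda i: (records[i].year, records[i].first_author, records[i].study_id),
    )
    full = meta_analyze(effects, min_k=2)
    if rule == "first_published":
        drop = order[0]
    else:
        direction = full.pooled_log_or if full.pooled_log_or != 0 else 1.0
        positives = [
            i for i in order if _is_positive(records[i], effects[i], direction)
        ]
        if not positives:
            # No individually positive study to drop: pool unchanged.
            return full, True
        drop = positives[0]

    kept = [e for i, e in enumerate(effects) if i != drop]
    repooled = meta_analyze(
        kept, variant_id=full.variant_id, stratum=full.stratum, min_k=2
    )
    retained = not (repooled.ci_low <= 1.0 <= repooled.ci_high)
    return repooled, retained


def assess_bias(
    effects: Sequence[EffectEstimate],
    records: Sequence[StudyRecord],
    bias_alpha: float = 0.10,
) -> BiasAssessment:
    """Run Egger, Begg and both sensitivity exclusions; collect flags.

    With fewer than three studies the rank/regression tests are reported
    as not computable (None) rather than raising.
    """
    egger_i = egger_se = egger_p = begg_z = begg_p = None
    retained_pub = retained_pos = True
    if len(effects) >= 3:
        try:
            egger_i, egger_se, egger_p = egger_test(effects)
        except InsufficientDataError:
            pass  # e.g. no variation in precision: reported as not computable
        begg_z, begg_p = begg_test(effects)
        _, retained_pub = sensitivity_exclude(effects, records, "first_published")
        _, retained_pos = sensitivity_exclude(effects, records, "first_positive")
    return BiasAssessment(
        egger_intercept=egger_i,
        egger_se=egger_se,
        egger_p=egger_p,
        begg_statistic=begg_z,
        begg_p=begg_p,
        sensitivity_first_published_retained=retained_pub,
        sensitivity_first_positive_retained=retained_pos,
        bias_alpha=bias_alpha,
    )
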