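"""Venice-criteria letter grades, FPRP, and cumulative-evidence integration.

A significant association receives three letters (A/B/C) for amount of
evidence, replication, and protection from bias; the composite level is
strong (all A), weak (any C), or moderate otherwise.  The false-positive
report probability

    FPRP = α(1−π) / (α(1−π) + power·π)

is computed at α equal to the observed P, with power the two-sided
probability of detecting a log OR of ±ln(detectable OR) at that α, and
prior probability π of a true association.  FPRP < 0.05 upgrades the
composite one level; FPRP > 0.20 downgrades it one level.
"""

from __future__ import annotations

import math
from typing import Optional

from scipy import stats

from .records import (
    BiasAssessment,
    CumulativeEvidence,
    EligibilityError,
    FPRPResult,
    MetaResult,
    ValidationError,
    VeniceGrade,
)

__all__ = [
    "grade_amount",
    "grade_replication",
    "grade_bias",
    "fprp",
    "fprp_value",
    "classify_fprp",
    "composite_venice",
    "integrate_evidence",
    "grade_association",
    "DEFAULT_FPRP_PRIOR",
    "DEFAULT_DETECTABLE_OR",
]

DEFAULT_FPRP_PRIOR = 0.05
DEFAULT_DETECTABLE_OR = 1.5

# Amount-of-evidence thresholds on the total test-allele count.
AMOUNT_A_ABOVE = 1000
AMOUNT_B_FLOOR = 100

_LEVELS = ("weak", "moderate", "strong")


def grade_amount(
    total_test_allele_count: Optional[int],
    fallback_n: Optional[int] = None,
    fallback_freq: float = 0.25,
) -> str:
    """Amount-of-evidence letter from the total test-allele count.

    A above 1000 alleles, B for 100–1000 (both ends inclusive), C below
    100.  When allele counts are unavailable, an approximate count
    2·N·frequency is formed from the total sample size N.
    """
    count = total_test_allele_count
    if count is None:
        if fallback_n is None:
            raise EligibilityError(
                "amount grading needs a test-allele count or a fallback sample size"
            )
        count = 2.0 * fallback_n * fallback_freq
    if count < 0:
        raise ValidationError(f"allele count must be non-negative, got {count}")
    if count > AMOUNT_A_ABOVE:
        return "A"
    if count >= AMOUNT_B_FLOOR:
        return "B"
    return "C"


def grade_replication(i_squared_percent: float) -> str:
    """Replication letter from heterogeneity: A if I²<25, B if 25–50, C if >50."""
    if not (0.0 <= i_squared_percent <= 100.0):
        raise ValueError(f"I² must be in [0, 100], got {i_squared_percent}")
    if i_squared_percent < 25.0:
        return "A"
    if i_squared_percent <= 50.0:
        return "B"
    return "C"


def grade_bias(assessment: BiasAssessment) -> str:
    """Protection-from-bias letter.

    C when any of publication bias, small-study bias, or loss of
    significance in sensitivity analysis is flagged; B when the tests
    were not computable; A otherwise.
    """
    if assessment.sensitivity_loss or assessment.small_study_bias or assessment.publication_bias:
        return "C"
    if not assessment.computable:
        return "B"
    return "A"


def fprp_value(alpha_obs: float, power: float, prior: float) -> float:
    """Raw FPRP formula: α(1−π) / (α(1−π) + power·π)."""
    return alpha_obs * (1.0 - prior) / (alpha_obs * (1.0 - prior) + power * prior)


def fprp(
    alpha_obs: float,
    se: float,
    direction: float = 1.0,
    prior: float = DEFAULT_FPRP_PRIOR,
    detectable_or: float = DEFAULT_DETECTABLE_OR,
) -> FPRPResult:
    """False-positive report probability at α equal to the observed P.

    ``direction`` is the sign of the pooled log OR; for protective
    effects the detectable effect is 1/detectable_or, which on the log
    scale has the same magnitude, so only |ln OR₀|/se enters the power.
    """
    if not (0.0 < alpha_obs <= 1.0):
        raise ValueError(f"observed P must be in (0, 1], got {alpha_obs}")
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    if not (0.0 < prior < 1.0):
        raise ValueError(f"prior must be in (0, 1), got {prior}")
    if detectable_or <= 1.0:
        raise ValueError(f"detectable OR must exceed 1, got {detectable_or}")
    theta0 = abs(math.log(detectable_or))
    z_half = stats.norm.isf(alpha_obs / 2.0)
    ncp = theta0 / se
    power = float(stats.norm.cdf(-z_half + ncp) + stats.norm.cdf(-z_half - ncp))
    power = min(max(power, 1e-300), 1.0)
    value = fprp_value(alpha_obs, power, prior)
    return FPRPResult(
        prior=prior,
        detectable_or=detectable_or,
        alpha_obs=alpha_obs,
        power=power,
        fprp=value,
        fprp_class=classify_fprp(value),
    )


def classify_fprp(value: float) -> str:
    """strong below 0.05, weak above 0.20, moderate between (bounds inclusive)."""
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"FPRP must be in [0, 1], got {value}")
    if value < 0.05:
        return "strong"
    if value > 0.20:
        return "weak"
    return "moderate"


def composite_venice(grade: VeniceGrade) -> str:
    """strong iff AAA; weak if any C; moderate otherwise."""
    letters = (grade.amount, grade.replication, grade.bias)
    if all(l == "A" for l in letters):
        return "strong"
    if any(l == "C" for l in letters):
        return "weak"
    return "moderate"


def integrate_evidence(venice_composite: str, fprp_class: str) -> str:
    """One-level FPRP adjustment of the composite Venice level.

    Upgrade one level when FPRP evidence is strong (capped at strong),
    downgrade one level when weak (floored at weak), unchanged when
    moderate.
    """
    if venice_composite not in _LEVELS:
        raise ValueError(f"unknown evidence level {venice_composite!r}")
    if fprp_class not in _LEVELS:
        raise ValueError(f"unknown FPRP class {fprp_class!r}")
    idx = _LEVELS.index(venice_composite)
    if fprp_class == "strong":
        idx = min(idx + 1, 2)
    elif fprp_class == "weak":
        idx = max(idx - 1, 0)
    return _LEVELS[idx]


def grade_association(
    meta: MetaResult,
    bias: BiasAssessment,
    total_test_allele_count: Optional[int] = None,
    fallback_n: Optional[int] = None,
    fprp_prior: float = DEFAULT_FPRP_PRIOR,
    fprp_detectable_or: float = DEFAULT_DETECTABLE_OR,
) -> CumulativeEvidence:
    """Full grading of one significant association (P < 0.05 required)."""
    if not meta.significant:
        raise EligibilityError(
            f"{meta.variant_id or 'association'}: grading applies only to "
            f"associations with P < 0.05 (got P = {meta.p_value:.3g})"
        )
    venice = VeniceGrade(
        amount=grade_amount(total_test_allele_count, fallback_n=fallback_n),
        replication=grade_replication(meta.i_squared),
        bias=grade_bias(bias),
    )
    composite = composite_venice(venice)
    fprp_res = fprp(
        alpha_obs=meta.p_value,
        se=meta.pooled_se,
        direction=math.copysign(1.0, meta.pooled_log_or) if meta.pooled_log_or else 1.0,
        prior=fprp_prior,
        detectable_or=fprp_detectable_or,
    )
    final = integrate_evidence(composite, fprp_res.fprp_class)
    return CumulativeEvidence(
        venice=venice,
        venice_composite=composite,
        fprp=fprp_res,
        final_level=final,
    )
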