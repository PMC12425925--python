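"""Per-study effect computation under the additive (allelic) model.

A study contributes one 2x2 table of test vs reference allele by
case/control status.  The log odds ratio and its Woolf standard error
are ln(ad/bc) and sqrt(1/a + 1/b + 1/c + 1/d).  When a study only
reports an OR with a 95% CI, the standard error is reconstructed from
the CI width on the log scale.
"""

from __future__ import annotations

import math
from typing import Optional

from scipy import stats

from .records import EffectEstimate, StudyRecord, ValidationError

__all__ = ["Z_95", "effect_from_counts", "se_from_ci", "effect_from_study", "wald_p"]

# Fixed normal quantile for 95% intervals so CI inversions are bit-reproducible.
Z_95 = 1.959964


def effect_from_counts(
    counts: tuple[float, float, float, float],
    zero_cell_rule: str = "haldane",
    study_id: str = "",
) -> EffectEstimate:
    """Allelic log OR and Woolf SE from a (a, b, c, d) table.

    With the Haldane–Anscombe rule, 0.5 is added to every cell whenever
    any cell is zero; with ``zero_cell_rule="none"`` a zero cell raises.
    """
    if len(counts) != 4 or any(c < 0 for c in counts):
        raise ValidationError(f"counts must be four non-negative values, got {counts}")
    a, b, c, d = (float(x) for x in counts)
    if min(a, b, c, d) == 0.0:
        if zero_cell_rule == "haldane":
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        elif zero_cell_rule == "none":
            raise ValidationError(
                f"degenerate 2x2 table with a zero cell: {counts}"
            )
        else:
            raise ValueError(f"unknown zero_cell_rule {zero_cell_rule!r}")
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return EffectEstimate(study_id=study_id, log_or=log_or, se=se)


def se_from_ci(ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """SE of the log OR reconstructed from a CI on the OR scale."""
    if not (0 < ci_low < ci_high):
        raise ValueError(f"require 0 < ci_low < ci_high, got ({ci_low}, {ci_high})")
    if not (0 < level < 1):
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    if level == 0.95:
        z = Z_95
    else:
        z = stats.norm.ppf(0.5 + level / 2.0)
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * z)


def effect_from_study(
    record: StudyRecord, zero_cell_rule: str = "haldane"
) -> EffectEstimate:
    """Effect estimate for one study: counts preferred, CI fallback."""
    if record.allele_counts is not None:
        return effect_from_counts(
            record.allele_counts, zero_cell_rule=zero_cell_rule, study_id=record.study_id
        )
    return EffectEstimate(
        study_id=record.study_id,
        log_or=math.log(record.reported_or),
        se=se_from_ci(record.ci_low, record.ci_high),
    )


def wald_p(log_or: float, se: float) -> float:
    """Two-sided Wald P for a log OR against zero."""
    z = abs(log_or) / se
    return float(2.0 * stats.norm.sf(z))
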