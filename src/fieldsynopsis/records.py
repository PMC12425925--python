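"""Domain records for a genetic-association field synopsis.

The unit of data is the *published study summary*: one row per
(study, variant, ancestry stratum), carrying either a 2x2 allele-count
table (test vs reference allele by case/control status) or a reported
odds ratio with its 95% confidence interval.  Everything downstream
(pooling, heterogeneity, bias tests, evidence grading) consumes these
records.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "SynopsisError",
    "ValidationError",
    "EligibilityError",
    "InsufficientDataError",
    "StudyRecord",
    "EffectEstimate",
    "MetaResult",
    "SubgroupResult",
    "MetaRegressionResult",
    "BiasAssessment",
    "VeniceGrade",
    "FPRPResult",
    "CumulativeEvidence",
    "GwasRecord",
    "VariantTable",
    "normalize_variant_id",
]

ANCESTRIES = ("Asian", "Caucasian", "Other")


class SynopsisError(Exception):
    """Base class for all package errors."""


class ValidationError(SynopsisError):
    """A record or sheet violates an invariant."""


class EligibilityError(SynopsisError):
    """An analysis was requested on data that does not meet its entry rules."""


class InsufficientDataError(SynopsisError):
    """Too few studies for a statistic to be defined (k below its floor)."""


_RSID_RE = re.compile(r"^rs\d+$", re.IGNORECASE)


def normalize_variant_id(raw: str) -> str:
    """Collapse variant-naming dialects onto one key space.

    rsIDs are lower-cased (``RS7574865`` -> ``rs7574865``).  HLA allele
    names are upper-cased with colons removed, so the two-field forms
    ``DQB1*03:01`` and ``DQB1*0301`` map to the same key.  Anything else
    (e.g. promoter-position labels like ``-1082 G/A``) is returned with
    surrounding whitespace stripped.  Idempotent.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise ValueError("variant identifier must be a non-empty string")
    s = raw.strip()
    if _RSID_RE.match(s):
        return s.lower()
    if "*" in s:
        return s.upper().replace(":", "")
    return s


@dataclass(frozen=True)
class StudyRecord:
    """One study-level observation of a variant.

    ``allele_counts`` is (a, b, c, d): test-allele count in cases,
    reference-allele count in cases, test-allele count in controls,
    reference-allele count in controls.
    """

    study_id: str
    first_author: str
    year: int
    ancestry: str
    variant_id: str
    gene: str
    n_cases: int
    n_controls: int
    allele_counts: Optional[tuple[int, int, int, int]] = None
    reported_or: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    diagnostic_criteria: str = ""
    genotyping_method: str = ""
    partial_typing: bool = False

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValidationError(
                f"{self.study_id}/{self.variant_id}: case and control counts must be positive"
            )
        if self.ancestry not in ANCESTRIES:
            raise ValidationError(
                f"{self.study_id}/{self.variant_id}: ancestry {self.ancestry!r} "
                f"not one of {ANCESTRIES}"
            )
        has_ci = (
            self.reported_or is not None
            and self.ci_low is not None
            and self.ci_high is not None
        )
        if self.allele_counts is None and not has_ci:
            raise ValidationError(
                f"{self.study_id}/{self.variant_id}: need allele counts or "
                "(reported_or, ci_low, ci_high)"
            )
        if has_ci:
            if not (0 < self.ci_low <= self.reported_or <= self.ci_high):
                raise ValidationError(
                    f"{self.study_id}/{self.variant_id}: require "
                    f"0 < ci_low <= OR <= ci_high, got "
                    f"({self.ci_low}, {self.reported_or}, {self.ci_high})"
                )
        if self.allele_counts is not None:
            counts = self.allele_counts
            if len(counts) != 4 or any(
                (not float(c).is_integer()) or c < 0 for c in counts
            ):
                raise ValidationError(
                    f"{self.study_id}/{self.variant_id}: allele counts must be four "
                    "non-negative integers"
                )
            a, b, c, d = counts
            if not self.partial_typing:
                if a + b != 2 * self.n_cases:
                    raise ValidationError(
                        f"{self.study_id}/{self.variant_id}: case allele total "
                        f"{a + b} != 2*n_cases ({2 * self.n_cases}); "
                        "set partial_typing=True for incompletely typed studies"
                    )
                if c + d != 2 * self.n_controls:
                    raise ValidationError(
                        f"{self.study_id}/{self.variant_id}: control allele total "
                        f"{c + d} != 2*n_controls ({2 * self.n_controls})"
                    )
        object.__setattr__(self, "variant_id", normalize_variant_id(self.variant_id))

    @property
    def test_allele_total(self) -> Optional[int]:
        """Total test-allele count across both arms (amount-of-evidence input)."""
        if self.allele_counts is None:
            return None
        a, _, c, _ = self.allele_counts
        return a + c


@dataclass(frozen=True)
class EffectEstimate:
    """Per-study log odds ratio with its standard error."""

    study_id: str
    log_or: float
    se: float

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValidationError(f"{self.study_id}: se must be positive, got {self.se}")

    @property
    def weight_fixed(self) -> float:
        return 1.0 / (self.se * self.se)

    @property
    def variance(self) -> float:
        return self.se * self.se


@dataclass(frozen=True)
class MetaResult:
    """Pooled effect for one variant/stratum."""

    variant_id: str
    stratum: str
    model: str  # "fixed" | "random"
    k: int
    pooled_log_or: float
    pooled_se: float
    ci_low: float  # OR scale
    ci_high: float  # OR scale
    p_value: float
    q_stat: float
    q_df: int
    q_p: float
    i_squared: float  # percent
    tau_squared: float

    def __post_init__(self) -> None:
        if self.model not in ("fixed", "random"):
            raise ValidationError(f"unknown model {self.model!r}")

    @property
    def pooled_or(self) -> float:
        return math.exp(self.pooled_log_or)

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass(frozen=True)
class SubgroupResult:
    per_subgroup: Mapping[str, MetaResult]
    q_between: float
    df_between: int
    p_interaction: float


@dataclass(frozen=True)
class MetaRegressionResult:
    covariate: str
    coefficient: float
    se: float
    p_value: float
    tau_squared_residual: float


@dataclass(frozen=True)
class BiasAssessment:
    """Publication/small-study bias tests and sensitivity-retention flags.

    ``egger_p``/``begg_p`` are None when the test was not computable
    (fewer than three studies).
    """

    egger_intercept: Optional[float] = None
    egger_se: Optional[float] = None
    egger_p: Optional[float] = None
    begg_statistic: Optional[float] = None
    begg_p: Optional[float] = None
    sensitivity_first_published_retained: bool = True
    sensitivity_first_positive_retained: bool = True
    bias_alpha: float = 0.10

    @property
    def computable(self) -> bool:
        return self.egger_p is not None and self.begg_p is not None

    @property
    def publication_bias(self) -> bool:
        return self.begg_p is not None and self.begg_p < self.bias_alpha

    @property
    def small_study_bias(self) -> bool:
        return self.egger_p is not None and self.egger_p < self.bias_alpha

    @property
    def sensitivity_loss(self) -> bool:
        return not (
            self.sensitivity_first_published_retained
            and self.sensitivity_first_positive_retained
        )

    @property
    def flags(self) -> frozenset[str]:
        out = set()
        if self.publication_bias:
            out.add("publication_bias")
        if self.small_study_bias:
            out.add("small_study_bias")
        if self.sensitivity_loss:
            out.add("sensitivity_loss")
        return frozenset(out)


_LETTERS = ("A", "B", "C")
_LEVELS = ("weak", "moderate", "strong")


@dataclass(frozen=True)
class VeniceGrade:
    """Three-letter credibility grade: amount, replication, protection from bias."""

    amount: str
    replication: str
    bias: str

    def __post_init__(self) -> None:
        for letter in (self.amount, self.replication, self.bias):
            if letter not in _LETTERS:
                raise ValidationError(f"Venice letters must be A/B/C, got {letter!r}")

    @classmethod
    def from_string(cls, triplet: str) -> "VeniceGrade":
        t = triplet.strip().upper()
        if len(t) != 3:
            raise ValidationError(f"expected a three-letter grade, got {triplet!r}")
        return cls(t[0], t[1], t[2])

    def __str__(self) -> str:
        return self.amount + self.replication + self.bias


@dataclass(frozen=True)
class FPRPResult:
    prior: float
    detectable_or: float
    alpha_obs: float
    power: float
    fprp: float
    fprp_class: str  # strong | moderate | weak


@dataclass(frozen=True)
class CumulativeEvidence:
    venice: VeniceGrade
    venice_composite: str
    fprp: Optional[FPRPResult]
    final_level: str

    def __post_init__(self) -> None:
        for lvl in (self.venice_composite, self.final_level):
            if lvl not in _LEVELS:
                raise ValidationError(f"unknown evidence level {lvl!r}")


@dataclass(frozen=True)
class GwasRecord:
    """One catalogue row: the lead variant reported for a locus/ancestry."""

    locus: str
    gene: str
    ancestry_group: str
    lead_variant: str
    n_cases: int
    n_controls: int
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float
    ld_variants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.lead_variant:
            raise ValidationError("lead_variant must be non-empty")
        object.__setattr__(self, "lead_variant", normalize_variant_id(self.lead_variant))
        object.__setattr__(
            self, "ld_variants", tuple(normalize_variant_id(v) for v in self.ld_variants)
        )

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class VariantTable:
    """Validated study records grouped by normalized variant id."""

    records: list[StudyRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for rec in self.records:
            key = (rec.study_id, rec.variant_id, rec.ancestry)
            if key in seen:
                raise ValidationError(f"duplicate (study, variant, ancestry) triple {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def variant_ids(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.variant_id not in out:
                out.append(rec.variant_id)
        return out

    def group(self, variant_id: str) -> list[StudyRecord]:
        key = normalize_variant_id(variant_id)
        return [r for r in self.records if r.variant_id == key]

    def groups(self) -> dict[str, list[StudyRecord]]:
        out: dict[str, list[StudyRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.variant_id, []).append(rec)
        return out

    def extend(self, records: Iterable[StudyRecord]) -> None:
        for rec in records:
            self.records.append(rec)
        # re-check duplicate invariant
        self.__post_init__()
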