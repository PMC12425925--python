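"""End-to-end synopsis orchestration.

Eligibility filtering (sample-size floor, minimum independent datasets),
per-variant meta-analysis with ethnicity subgroups, bias assessment,
Venice/FPRP grading, significance tiering (nominal and genome-wide),
GWAS lead-variant reconciliation, and the phenome-wide Bonferroni
threshold.  Also provides the printed-table replay used when only the
published pooled columns — not the per-study data — are available.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence, Union

import yaml

from .bias import assess_bias
from .effects import effect_from_study, se_from_ci, wald_p
from .grading import (
    classify_fprp,
    composite_venice,
    fprp,
    grade_association,
    grade_replication,
    integrate_evidence,
)
from .meta import meta_analyze, subgroup_analysis
from .published import (
    PublishedAssociation,
    gwas_catalogue,
    significant_associations,
)
from .records import (
    BiasAssessment,
    CumulativeEvidence,
    EligibilityError,
    GwasRecord,
    MetaResult,
    StudyRecord,
    SubgroupResult,
    SynopsisError,
    VariantTable,
    VeniceGrade,
    normalize_variant_id,
)
from .sheets import (
    ReadReport,
    read_extraction_sheet,
    read_gwas_sheet,
    synopsis_row,
    write_synopsis_table,
)

__all__ = [
    "SynopsisConfig",
    "VariantSynopsis",
    "SynopsisReport",
    "filter_eligible",
    "significance_tiers",
    "select_gwas_leads",
    "overlap_with_gwas",
    "phewas_threshold",
    "run_synopsis",
    "replay_published_synopsis",
]


@dataclass(frozen=True)
class SynopsisConfig:
    """All synopsis thresholds in one place.

    Defaults encode the synopsis protocol: studies need at least 50
    cases and 50 controls; a variant needs three independent datasets
    (two per stratum for subgroup analysis); bias tests flag at P<0.10;
    FPRP uses prior 0.05 and detectable OR 1.5; genome-wide significance
    at 5e-8.
    """

    min_cases: int = 50
    min_controls: int = 50
    min_datasets: int = 3
    subgroup_min_datasets: int = 2
    alpha_nominal: float = 0.05
    alpha_gw: float = 5.0e-8
    bias_alpha: float = 0.10
    fprp_prior: float = 0.05
    fprp_detectable_or: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_cases", "min_controls", "min_datasets",
                     "subgroup_min_datasets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.alpha_gw < self.alpha_nominal):
            raise ValueError("require 0 < alpha_gw < alpha_nominal")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SynopsisConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8"
        )


@dataclass
class VariantSynopsis:
    """Everything the synopsis knows about one variant."""

    variant_id: str
    gene: str
    primary: Optional[MetaResult]
    strata: dict[str, MetaResult] = dc_field(default_factory=dict)
    subgroup: Optional[SubgroupResult] = None
    bias: Optional[BiasAssessment] = None
    evidence: Optional[CumulativeEvidence] = None
    tiers: frozenset[str] = frozenset()
    gwas_overlap: bool = False
    notes: list[str] = dc_field(default_factory=list)

    @property
    def is_hla(self) -> bool:
        return "*" in self.variant_id


@dataclass
class SynopsisReport:
    variants: list[VariantSynopsis]
    exclusions: list[dict[str, Any]]
    read_errors: list[dict[str, Any]]
    summary: dict[str, Any]


def filter_eligible(
    table: VariantTable, config: SynopsisConfig = SynopsisConfig()
) -> tuple[VariantTable, list[dict[str, Any]]]:
    """Apply the sample-size floor then the minimum-datasets rule.

    Every exclusion is logged with the rule that fired; the eligible set
    plus the log partition the input exactly.
    """
    log: list[dict[str, Any]] = []
    kept: list[StudyRecord] = []
    for rec in table.records:
        if rec.n_cases < config.min_cases:
            log.append({"study_id": rec.study_id, "variant_id": rec.variant_id,
                        "rule": "min_cases", "value": rec.n_cases})
        elif rec.n_controls < config.min_controls:
            log.append({"study_id": rec.study_id, "variant_id": rec.variant_id,
                        "rule": "min_controls", "value": rec.n_controls})
        else:
            kept.append(rec)
    counts = Counter(rec.variant_id for rec in kept)
    final: list[StudyRecord] = []
    for rec in kept:
        if counts[rec.variant_id] < config.min_datasets:
            log.append({"study_id": rec.study_id, "variant_id": rec.variant_id,
                        "rule": "min_datasets", "value": counts[rec.variant_id]})
        else:
            final.append(rec)
    return VariantTable(records=final, provenance=table.provenance), log


def significance_tiers(
    meta: MetaResult, config: SynopsisConfig = SynopsisConfig()
) -> frozenset[str]:
    """{nominal} ∪ {genome_wide}: P < 0.05 and P < 5e-8 respectively."""
    tiers = set()
    if meta.p_value < config.alpha_nominal:
        tiers.add("nominal")
    if meta.p_value < config.alpha_gw:
        tiers.add("genome_wide")
    return frozenset(tiers)


def select_gwas_leads(records: Sequence[GwasRecord]) -> list[GwasRecord]:
    """One record per (locus, ancestry group): the largest total sample.

    Ties break on smaller P, then lexicographic variant id; selection is
    order-invariant.
    """
    best: dict[tuple[str, str], GwasRecord] = {}
    for rec in records:
        key = (rec.locus, rec.ancestry_group)
        cur = best.get(key)
        if cur is None:
            best[key] = rec
            continue
        cand = (-rec.n_total, rec.p_value, rec.lead_variant)
        incumbent = (-cur.n_total, cur.p_value, cur.lead_variant)
        if cand < incumbent:
            best[key] = rec
    return [best[k] for k in sorted(best)]


def overlap_with_gwas(
    meta_significant: Iterable[str],
    gwas_leads: Sequence[GwasRecord],
    include_ld: bool = False,
) -> set[str]:
    """Variants found by both approaches (normalized-id intersection)."""
    sig = {normalize_variant_id(v) for v in meta_significant}
    catalogue = {rec.lead_variant for rec in gwas_leads}
    if include_ld:
        for rec in gwas_leads:
            catalogue.update(rec.ld_variants)
    return sig & catalogue


def phewas_threshold(n_phenotypes: int, alpha: float = 0.05) -> float:
    """Bonferroni phenome-wide threshold alpha/n, to 3 significant digits."""
    if n_phenotypes < 1:
        raise ValueError(f"n_phenotypes must be >= 1, got {n_phenotypes}")
    return float(f"{alpha / n_phenotypes:.2e}")


def _analyze_variant(
    variant_id: str,
    records: list[StudyRecord],
    config: SynopsisConfig,
) -> VariantSynopsis:
    effects = [effect_from_study(rec) for rec in records]
    primary = meta_analyze(
        effects, variant_id=variant_id, stratum="All ancestries",
        min_k=config.min_datasets,
    )
    syn = VariantSynopsis(
        variant_id=variant_id, gene=records[0].gene, primary=primary,
        strata={"All ancestries": primary},
    )
    labels = [rec.ancestry for rec in records]
    eligible_strata = {
        lab for lab in set(labels)
        if labels.count(lab) >= config.subgroup_min_datasets
    }
    if len(eligible_strata) >= 2:
        sub = subgroup_analysis(
            effects, labels, min_per_group=config.subgroup_min_datasets,
            variant_id=variant_id,
        )
        syn.subgroup = sub
        syn.strata.update(sub.per_subgroup)
    if len(effects) >= 3:
        syn.bias = assess_bias(effects, records, bias_alpha=config.bias_alpha)
    syn.tiers = significance_tiers(primary, config)
    if "nominal" in syn.tiers and syn.bias is not None:
        totals = [rec.test_allele_total for rec in records]
        total_alleles = sum(t for t in totals if t is not None) if any(
            t is not None for t in totals
        ) else None
        fallback = sum(rec.n_cases + rec.n_controls for rec in records)
        syn.evidence = grade_association(
            primary, syn.bias,
            total_test_allele_count=total_alleles,
            fallback_n=fallback,
            fprp_prior=config.fprp_prior,
            fprp_detectable_or=config.fprp_detectable_or,
        )
    return syn


def _summarize(
    variants: list[VariantSynopsis], overlap: set[str]
) -> dict[str, Any]:
    sig = [v for v in variants if "nominal" in v.tiers]
    letters = Counter()
    for v in sig:
        if v.evidence is not None:
            g = v.evidence.venice
            letters["amount_" + g.amount] += 1
            letters["replication_" + g.replication] += 1
            letters["bias_" + g.bias] += 1
    evidence_levels = Counter(
        v.evidence.final_level for v in sig if v.evidence is not None
    )
    fprp_classes = Counter(
        v.evidence.fprp.fprp_class for v in sig
        if v.evidence is not None and v.evidence.fprp is not None
    )
    return {
        "n_variants": len(variants),
        "n_significant": len(sig),
        "n_significant_hla": sum(1 for v in sig if v.is_hla),
        "n_significant_non_hla": sum(1 for v in sig if not v.is_hla),
        "n_genome_wide": sum(1 for v in variants if "genome_wide" in v.tiers),
        "evidence_levels": dict(evidence_levels),
        "venice_letters": dict(letters),
        "fprp_classes": dict(fprp_classes),
        "n_gwas_overlap": len(overlap),
        "gwas_overlap": sorted(overlap),
    }


def run_synopsis(
    extraction_path: Union[str, Path],
    gwas_path: Optional[Union[str, Path]] = None,
    config: SynopsisConfig = SynopsisConfig(),
    dialect: str = "tsv",
) -> SynopsisReport:
    """Full pipeline from an extraction sheet to a graded synopsis."""
    report = read_extraction_sheet(extraction_path, dialect=dialect)
    eligible, exclusions = filter_eligible(report.table, config)
    gwas_leads: list[GwasRecord] = []
    if gwas_path is not None:
        gwas_leads = select_gwas_leads(read_gwas_sheet(gwas_path, dialect=dialect))
    variants: list[VariantSynopsis] = []
    for variant_id, records in sorted(eligible.groups().items()):
        try:
            variants.append(_analyze_variant(variant_id, records, config))
        except SynopsisError as exc:  # isolate per-variant failures
            variants.append(VariantSynopsis(
                variant_id=variant_id, gene=records[0].gene,
                primary=None, notes=[f"failed: {exc}"],
            ))
    ok = [v for v in variants if v.primary is not None]
    overlap = overlap_with_gwas(
        [v.variant_id for v in ok if "nominal" in v.tiers], gwas_leads,
    ) if gwas_leads else set()
    for v in ok:
        v.gwas_overlap = v.variant_id in overlap
    summary = _summarize(ok, overlap)
    return SynopsisReport(
        variants=variants, exclusions=exclusions,
        read_errors=report.errors, summary=summary,
    )


def report_rows(report: SynopsisReport) -> list[dict[str, str]]:
    """Flatten a report into the fixed synopsis-table layout."""
    rows = []
    for v in report.variants:
        if v.primary is None:
            continue
        ev = v.evidence
        rows.append(synopsis_row(
            v.variant_id, v.gene, v.primary.stratum, v.primary.model,
            v.primary.k, v.primary.pooled_or, v.primary.ci_low,
            v.primary.ci_high, v.primary.p_value, v.primary.i_squared,
            venice=str(ev.venice) if ev else "",
            fprp=ev.fprp.fprp if ev and ev.fprp else None,
            evidence=ev.final_level if ev else "",
        ))
    return rows


# --- Printed-table replay --------------------------------------------------

def replay_published_synopsis(
    associations: Optional[Sequence[PublishedAssociation]] = None,
    gwas: Optional[Sequence[GwasRecord]] = None,
    include_ld: bool = False,
    alpha_gw: float = 5.0e-8,
) -> dict[str, Any]:
    """Re-run the grading/tier stages on the printed synopsis columns.

    The per-study datasets behind the published pooled estimates are not
    available, so the printed intermediate columns (OR, CI, P, I²,
    Venice letters, FPRP) serve as stage inputs.  Returns per-variant
    rows plus the summary counts (evidence levels, replication letters,
    FPRP classes, significance tiers, GWAS overlap).
    """
    if associations is None:
        associations = significant_associations()
    if gwas is None:
        gwas = gwas_catalogue()

    per_variant: list[dict[str, Any]] = []
    for assoc in associations:
        venice = VeniceGrade.from_string(assoc.venice)
        composite = composite_venice(venice)
        fprp_class = classify_fprp(assoc.fprp_value)
        final = integrate_evidence(composite, fprp_class)
        replication_letter = grade_replication(assoc.primary.i_squared)
        tiers = {"nominal"}  # table rows are the significant associations
        if assoc.primary.p_value < alpha_gw:
            tiers.add("genome_wide")
        per_variant.append({
            "variant_id": assoc.variant_id,
            "gene": assoc.gene,
            "region": assoc.region,
            "stratum": assoc.primary.ethnicity,
            "printed_venice": assoc.venice,
            "printed_cumulative": assoc.cumulative,
            "venice_composite": composite,
            "fprp_class": fprp_class,
            "final_level": final,
            "replication_letter": replication_letter,
            "printed_replication_letter": assoc.venice[1],
            "tiers": tiers,
            "genome_wide": "genome_wide" in tiers,
        })

    leads = list(gwas)
    overlap = overlap_with_gwas(
        [row["variant_id"] for row in per_variant], leads, include_ld=include_ld,
    )
    for row in per_variant:
        row["gwas_overlap"] = row["variant_id"] in overlap

    further_gw = sorted(
        row["variant_id"] for row in per_variant
        if row["genome_wide"] and not row["gwas_overlap"]
        and row["final_level"] == "strong"
    )
    summary = {
        "n_significant": len(per_variant),
        "evidence_levels": dict(Counter(r["final_level"] for r in per_variant)),
        "replication_letters": dict(Counter(r["replication_letter"] for r in per_variant)),
        "fprp_classes": dict(Counter(r["fprp_class"] for r in per_variant)),
        "n_genome_wide_hla": sum(
            1 for r in per_variant if r["genome_wide"] and r["region"] == "HLA"
        ),
        "n_genome_wide_non_hla": sum(
            1 for r in per_variant if r["genome_wide"] and r["region"] == "non-HLA"
        ),
        "gwas_overlap": sorted(overlap),
        "n_gwas_overlap": len(overlap),
        "further_genome_wide": further_gw,
        "n_further_genome_wide": len(further_gw),
    }
    return {"rows": per_variant, "summary": summary}
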