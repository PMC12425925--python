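"""Synthetic multi-study candidate-gene literatures with known truth.

Each simulated study draws its own log OR from Normal(true log OR, τ²),
converts the control allele frequency p0 through the odds transform
p1 = OR·p0 / (1 − p0 + OR·p0), and samples allele counts binomially
(2N alleles per arm — allele-level sampling, since the pipeline's
additive model consumes allele 2x2 tables).  Optional publication bias
suppresses each study whose own P >= 0.05 with a configured
probability.  Per-variant RNG substreams are derived from
(seed, variant index) so adding variants never perturbs earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence, Union

import numpy as np

from .effects import effect_from_study, wald_p
from .meta import meta_analyze
from .pipeline import SynopsisConfig, significance_tiers
from .records import StudyRecord, VariantTable

__all__ = [
    "SyntheticLiteratureConfig",
    "simulate_study",
    "simulate_literature",
    "recovery_experiment",
]

_ANCESTRY_POOL = ("Asian", "Caucasian")


@dataclass(frozen=True)
class SyntheticLiteratureConfig:
    """Generative truth for a simulated literature.

    ``true_log_or`` and ``control_allele_freq`` may be scalars or
    per-ancestry maps; ``studies_per_variant`` a count or (lo, hi)
    range; sample-size ranges default to realistic candidate-gene
    studies (100–2000 per arm, above the 50-subject eligibility floor).
    """

    n_variants: int = 1
    studies_per_variant: Union[int, tuple[int, int]] = 5
    true_log_or: Union[float, Mapping[str, float]] = 0.0
    tau_squared: float = 0.0
    control_allele_freq: Union[float, Mapping[str, float]] = 0.3
    n_cases_range: tuple[int, int] = (100, 2000)
    n_controls_range: tuple[int, int] = (100, 2000)
    ancestry_mix: Mapping[str, float] = field(
        default_factory=lambda: {"Asian": 0.5, "Caucasian": 0.5}
    )
    suppress_prob_nonsig: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.tau_squared < 0:
            raise ValueError("tau_squared must be non-negative")
        if not (0.0 <= self.suppress_prob_nonsig < 1.0):
            raise ValueError("suppress_prob_nonsig must be in [0, 1)")
        total = sum(self.ancestry_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ancestry proportions must sum to 1, got {total}")
        for rng_name in ("n_cases_range", "n_controls_range"):
            lo, hi = getattr(self, rng_name)
            if not (0 < lo <= hi):
                raise ValueError(f"{rng_name} must be a non-empty positive range")

    def _per_ancestry(self, value, ancestry: str) -> float:
        if isinstance(value, Mapping):
            return float(value[ancestry])
        return float(value)

    def log_or_for(self, ancestry: str) -> float:
        return self._per_ancestry(self.true_log_or, ancestry)

    def freq_for(self, ancestry: str) -> float:
        f = self._per_ancestry(self.control_allele_freq, ancestry)
        if not (0.0 < f < 1.0):
            raise ValueError(f"control allele frequency must be in (0,1), got {f}")
        return f


def case_allele_freq(odds_ratio: float, p0: float) -> float:
    """Odds transform: case frequency implied by OR and control frequency."""
    p1 = odds_ratio * p0 / (1.0 - p0 + odds_ratio * p0)
    if not (0.0 < p1 < 1.0):
        raise ValueError(
            f"case allele frequency {p1} outside (0,1) for OR={odds_ratio}, p0={p0}"
        )
    return p1


def simulate_study(
    true_log_or: float,
    tau_squared: float,
    control_af: float,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
    study_id: str = "sim",
    year: int = 2000,
    ancestry: str = "Asian",
    variant_id: str = "rs1",
    gene: str = "GENE",
    first_author: str = "Sim",
) -> StudyRecord:
    """One counts-bearing study under the allele-level binomial model."""
    theta = true_log_or
    if tau_squared > 0:
        theta = rng.normal(true_log_or, math.sqrt(tau_squared))
    p1 = case_allele_freq(math.exp(theta), control_af)
    a = int(rng.binomial(2 * n_cases, p1))
    c = int(rng.binomial(2 * n_controls, control_af))
    return StudyRecord(
        study_id=study_id,
        first_author=first_author,
        year=year,
        ancestry=ancestry,
        variant_id=variant_id,
        gene=gene,
        n_cases=n_cases,
        n_controls=n_controls,
        allele_counts=(a, 2 * n_cases - a, c, 2 * n_controls - c),
    )


def _variant_rng(seed: int, index: int) -> np.random.Generator:
    # independent substream per variant: adding variants never perturbs earlier ones
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def simulate_literature(
    config: SyntheticLiteratureConfig,
) -> tuple[VariantTable, list[dict[str, Any]]]:
    """Full extraction sheet plus a per-variant truth table.

    Publication bias: each study whose own two-sided P >= 0.05 is
    suppressed with probability ``suppress_prob_nonsig``; suppressions
    are logged in the truth table.
    """
    records: list[StudyRecord] = []
    truth: list[dict[str, Any]] = []
    ancestries = sorted(config.ancestry_mix)
    probs = np.array([config.ancestry_mix[a] for a in ancestries])
    for vi in range(config.n_variants):
        rng = _variant_rng(config.seed, vi)
        variant_id = f"rs{1000 + vi}"
        if isinstance(config.studies_per_variant, int):
            k = config.studies_per_variant
        else:
            lo, hi = config.studies_per_variant
            k = int(rng.integers(lo, hi + 1))
        n_suppressed = 0
        kept = 0
        for si in range(k):
            ancestry = ancestries[int(rng.choice(len(ancestries), p=probs))]
            n_cases = int(rng.integers(*config.n_cases_range, endpoint=True))
            n_controls = int(rng.integers(*config.n_controls_range, endpoint=True))
            rec = simulate_study(
                config.log_or_for(ancestry),
                config.tau_squared,
                config.freq_for(ancestry),
                n_cases,
                n_controls,
                rng,
                study_id=f"study_{vi}_{si}",
                year=1995 + si,
                ancestry=ancestry,
                variant_id=variant_id,
                gene=f"GENE{vi}",
                first_author=f"Author{si:02d}",
            )
            if config.suppress_prob_nonsig > 0.0:
                eff = effect_from_study(rec)
                p = wald_p(eff.log_or, eff.se)
                if p >= 0.05 and rng.random() < config.suppress_prob_nonsig:
                    n_suppressed += 1
                    continue
            records.append(rec)
            kept += 1
        truth.append({
            "variant_id": variant_id,
            "true_log_or": config.true_log_or
            if not isinstance(config.true_log_or, Mapping)
            else dict(config.true_log_or),
            "tau_squared": config.tau_squared,
            "n_studies_drawn": k,
            "n_studies_kept": kept,
            "n_suppressed": n_suppressed,
        })
    return VariantTable(records=records, provenance=f"simulated(seed={config.seed})"), truth


def recovery_experiment(
    config: SyntheticLiteratureConfig,
    n_replicates: int = 500,
    pipeline_config: SynopsisConfig = SynopsisConfig(),
) -> dict[str, Any]:
    """Repeatedly simulate one-variant literatures and measure recovery.

    Reports bias and RMSE of the selected-model pooled log OR, mean τ̂²,
    and the fraction of replicates reaching nominal significance.  Truth
    is the generating configuration (scalar effect assumed).
    """
    if isinstance(config.true_log_or, Mapping):
        raise ValueError("recovery_experiment expects a scalar true_log_or")
    est = np.empty(n_replicates)
    tau2 = np.empty(n_replicates)
    sig = np.zeros(n_replicates, dtype=bool)
    for rep in range(n_replicates):
        rep_config = SyntheticLiteratureConfig(
            **{**_config_dict(config), "seed": config.seed + rep}
        )
        table, _ = simulate_literature(rep_config)
        for variant_id, recs in table.groups().items():
            effects = [effect_from_study(r) for r in recs]
            result = meta_analyze(
                effects, variant_id=variant_id,
                min_k=min(pipeline_config.min_datasets, len(effects)),
            )
            est[rep] = result.pooled_log_or
            tau2[rep] = result.tau_squared
            sig[rep] = "nominal" in significance_tiers(result, pipeline_config)
    bias = float(np.mean(est) - config.true_log_or)
    return {
        "n_replicates": n_replicates,
        "true_log_or": config.true_log_or,
        "true_tau_squared": config.tau_squared,
        "mean_pooled_log_or": float(np.mean(est)),
        "bias_pooled_log_or": bias,
        "rmse_pooled_log_or": float(
            np.sqrt(np.mean((est - config.true_log_or) ** 2))
        ),
        "mean_tau_squared": float(np.mean(tau2)),
        "nominal_significance_rate": float(np.mean(sig)),
    }


def _config_dict(config: SyntheticLiteratureConfig) -> dict[str, Any]:
    return {
        "n_variants": config.n_variants,
        "studies_per_variant": config.studies_per_variant,
        "true_log_or": config.true_log_or,
        "tau_squared": config.tau_squared,
        "control_allele_freq": config.control_allele_freq,
        "n_cases_range": config.n_cases_range,
        "n_controls_range": config.n_controls_range,
        "ancestry_mix": dict(config.ancestry_mix),
        "suppress_prob_nonsig": config.suppress_prob_nonsig,
        "seed": config.seed,
    }
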