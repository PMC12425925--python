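# Methods

This note records the statistical model, the conventions and defaults,
the synthetic-data generator, and the design choices that were
genuinely open.

## Data model and per-study effects

The unit of data is the published study summary: one row per (study,
variant, ancestry stratum) carrying either a 2×2 allele-count table
(test vs reference allele by case/control status — the additive model)
or a reported OR with a 95% CI.  Records must satisfy structural
invariants (positive sample sizes, CI ordering `0 < lo ≤ OR ≤ hi`,
allele totals equal to twice the sample sizes unless flagged as
partially typed); violations are collected into an error report at read
time, never silently dropped, so the eligible set plus the error/
exclusion logs always partition the input.

Per-study effects use the Woolf formulas (log OR `ln(ad/bc)`, SE
`√(1/a+1/b+1/c+1/d)`).  Zero cells take the Haldane–Anscombe correction
— 0.5 added to **all four** cells, applied only when some cell is zero —
because it is the conventional default where a continuity rule is not
otherwise stated.  CI-only studies get `se = (ln hi − ln lo)/(2z)` with
the z quantile frozen at **1.959964** (not 1.96) so CI inversions are
bit-reproducible; `se_from_ci` and `effect_from_counts` agree to 1e-9
on a build-then-invert round trip.

Variant identifiers are normalized onto one key space (rsIDs
lower-cased; HLA alleles upper-cased with colons removed at two-field
resolution, so `DQB1*03:01` and `DQB1*0301` collide), since GWAS
catalogues and synopsis tables use different dialects and overlap
counting requires a single key space.  Normalization is idempotent;
identifiers that are neither rsIDs nor starred HLA alleles (e.g.
promoter labels like `-1082 G/A`) pass through unchanged.

## Pooling and heterogeneity

Fixed effects is inverse-variance weighting; heterogeneity is Cochran's
Q (flagged at P < 0.10) and I² = max(0,(Q−df)/Q)·100, with the bands
≤25% mild, 25–50% moderate, ≥50% large.  The model switch is **random
effects iff I² ≥ 50.0** (boundary inclusive, matching the rule's "≥"),
even though the replication letter treats I² = 50.0 as grade B — the
two rules are deliberately independent.  Random effects is
DerSimonian–Laird, the non-iterative moment estimator (the default in
the Stata tooling this field uses); REML is intentionally not
implemented.  Pooled P values are two-sided Wald tests on the log
scale, with no Knapp–Hartung adjustment.  Eligibility requires three
independent datasets per variant (two for sensitivity re-pools and
subgroup pools).

Between-subgroup heterogeneity: each stratum with ≥2 datasets is pooled
under its own I²-driven model switch (not the parent's), then
Q_between = Σ_g w_g(θ̂_g − θ̄)² with w_g the inverse squared pooled SE,
referred to χ² on (#groups − 1) df, flagged at P < 0.10.  With
fixed-effects pools throughout this decomposes exactly:
Q_total = ΣQ_within + Q_between (tested to 1e-9).  Whether a printed
"interaction P" in the source tables came from Q_between or from
meta-regression is not knowable; both are provided, and Q_between on
the printed subgroup CIs reproduces the printed `<0.001` flag for the
worked example (Q ≈ 13.3 against the χ²₁ 0.001 critical value 10.83).

Meta-regression is weighted least squares of θ̂ᵢ on one covariate with a
method-of-moments residual τ² (FE-weighted residual Q, the trace
correction for the design), re-weighted by 1/(seᵢ²+τ̂²); the slope is
tested with a Wald z.  The covariance is (XᵀWX)⁻¹ with W treated as
known — the meta-analytic convention, not OLS's scaled covariance —
which is why this small solver is written here rather than borrowed
from a generic regression routine.

## Bias tests and sensitivity

Egger: unweighted OLS of the standardized effect θ̂ᵢ/seᵢ on precision
1/seᵢ, intercept t-test on k−2 df (the classic form; weighted variants
were rejected to keep the flag semantics conventional).  Degenerate
inputs with no variation in precision are reported as not-computable
rather than crashing.  Begg–Mazumdar: Kendall's S between the
variance-standardized deviates (θ̂ᵢ−θ̂_FE)/√(vᵢ−v̄) and the vᵢ, normal
approximation with tie-corrected variance and **no continuity
correction** (so k=5 with perfect discordance gives z = −10/√(50/3)).
Both flag at P < 0.10 and need k ≥ 3; below that they are reported
not-computable, which maps to the bias letter B.

"First positive" in sensitivity analysis is interpreted as the
earliest-published study whose own 95% CI excludes OR 1 *in the
direction of the pooled estimate* (the term has no standard definition;
this reading keeps a contrarian significant study from counting as the
positive one).  Ties on year break on author then study id.  If no
study qualifies, the pool is returned unchanged with the retained flag
set.  "Retained" means the re-pooled 95% CI still excludes 1.  Bias
tests are computed wherever k ≥ 3, whether or not the pooled result is
significant; the grader consumes what it needs.

## Evidence grading

Amount of evidence uses the test-allele count thresholds (A above
1000, B 100–1000 inclusive, C below 100).  When allele counts are
unavailable the count is approximated as 2·N·frequency with a default
frequency of 0.25 — a mid-range allele frequency for the candidate
variants in this literature — and the approximation is inherent in the
letter, not hidden.  Replication comes from I² (A < 25, B 25–50,
C > 50).  Protection from bias is C if any of sensitivity loss,
small-study bias, or publication bias fires, B only when the tests were
not computable, A otherwise — in practice a binary A/C, matching the
observed letter distribution in the published tables (no middle-ground
B occurs there).

FPRP follows the Wacholder formulation with two conventions worth
stating.  (1) Power is evaluated at **α equal to the observed P**, not
at a fixed 0.05: power = Φ(−z_{α/2}+|θ₀|/se) + Φ(−z_{α/2}−|θ₀|/se)
with θ₀ = ln(detectable OR), which reproduces the `<0.001` classes of
genome-wide-significant rows under any reasonable prior.  (2) The
detectable effect is OR 1.5, inverted for protective effects — on the
log scale only |θ₀|/se enters, so direction never changes the value.
Defaults π = 0.05 and OR₀ = 1.5 are configuration, not dogma: published
mid-range FPRP magnitudes (e.g. a printed 0.15) depend on the original
authors' unstated conventions, so agreement is asserted at class level
(<0.05 / 0.05–0.20 / >0.20, boundaries mapping to moderate) rather
than at magnitude, except at the robust extremes.

Integration: composite Venice level (all A strong; any C weak; else
moderate), then one-level FPRP adjustment — upgrade if FPRP class is
strong (capped), downgrade if weak (floored), unchanged if moderate.
Replaying the printed letter triplets and FPRP values of all 44
significant associations in the bundled tables reproduces every printed
cumulative-evidence label and the 17/14/13 strong/moderate/weak tally.

## Pipeline conventions

Studies with fewer than 50 cases or 50 controls are excluded before the
three-dataset rule.  Tiering uses the primary row per variant (the
all-ancestries pool when present, otherwise the sole-ancestry pool):
nominal at P < 0.05, genome-wide at P < 5×10⁻⁸; subgroup rows never
confer tiers.  GWAS reconciliation keeps one lead variant per (locus,
ancestry group) — the largest total sample, ties broken by smaller P
then variant id — and overlap counting uses lead variants only by
default: LD-column variants are a separate, optional key space
(`include_ld=True`), because a variant tagged only through LD is
reported as an additional finding, not a dual identification.  The
phenome-wide threshold is the Bonferroni α/n reported to three
significant digits (0.05/778 → 6.43×10⁻⁵).

The published tables bundled in `fieldsynopsis.published` carry one
transcription judgement: a CI upper bound printed as "141" was recorded
as 1.41.  Printed "<0.001" values are stored as the bound with an
`is_bound` flag; a printed "0" is stored as 0.0.  Both classify
identically for grading purposes.

## Synthetic literatures

The generator emulates the data structure the pipeline consumes: per
variant, K studies each drawing θᵢ ~ Normal(μ, τ²), converting the
control allele frequency through the odds transform
p₁ = OR·p₀/(1−p₀+OR·p₀), and sampling allele counts binomially with
2N draws per arm.  Sampling is allele-level, not genotype-level —
the additive model consumes allele tables, so Hardy–Weinberg genotype
sampling would add machinery without changing any consumed statistic;
it is noted as an extension.  Defaults are a realistic candidate-gene
literature: five studies per variant, 100–2000 subjects per arm (above
the 50-subject floor), control allele frequency 0.3, equal Asian/
Caucasian mix.  Publication bias is significance-threshold suppression:
each study with its own P ≥ 0.05 is dropped with a configured
probability, and suppressions are logged in the truth table.  RNG
substreams derive from (seed, variant index), so enlarging a simulated
literature never perturbs earlier variants, and everything is
byte-reproducible under a fixed seed.

What the simulations do **not** model: linkage disequilibrium between
variants, haplotype-level HLA structure, genotyping error, covariate
adjustment differences between studies, or outcome-level selection
beyond the simple significance filter.  Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
generative model, not robustness to every failure mode of real
literatures.

Validation sizes (chosen to make Monte-Carlo error small relative to
the tolerances while keeping the default suite fast): fixed-effects
pooling is checked against a brute-force weighted mean on 1000 random
fixtures; DerSimonian–Laird recovery uses K = 50 studies of 2000 per
arm with τ² = 0.05 and OR = 1.3 over 500 replicates (observed |bias|
of the pooled log OR ≪ 0.02; mean τ̂² within 20% of truth); Egger's
type-I error under the null uses K = 10 over 1000 replicates (nominal
0.10, accepted band 0.07–0.13); the publication-bias injection uses a
modest true effect (OR 1.25, 50–400 per arm, K = 25 drawn studies) so
that significance-based suppression produces the textbook small-study
asymmetry — under an exactly null effect, two-sided suppression is
symmetric and produces little funnel asymmetry, so the null design
cannot demonstrate the monotone flag-rate response and was not used
for it.

## Known limitations

* DerSimonian–Laird is the only random-effects estimator; no REML,
  no Knapp–Hartung, no Bayesian or multivariate pooling.
* Only the additive allelic model; dominant/recessive 2×2 collapses of
  multi-allelic HLA loci (carrier vs allele counting) are supported as
  input conventions but the pipeline never asserts which one a source
  used.
* Bias is tested, never corrected (no trim-and-fill or selection
  models).
* FPRP magnitudes are convention-dependent (prior, detectable OR,
  power-at-α choice); only class labels are stable across reasonable
  conventions.
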