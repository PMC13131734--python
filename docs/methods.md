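# Methods

This note documents the statistical models implemented in `pleiomr`, the
choices made where the methodology leaves room, and what the simulation-based
tests do and do not establish.

## Conditional and conjunctional FDR

For a variant with p-values (p₁, p₂) in two traits, the conditional FDR is

    condFDR(p₁ | p₂) = p₁ / F̂(p₁ | p₂ < c),

the estimated posterior probability that the variant is null for trait 1
given its evidence in both traits. F̂ is the empirical CDF of primary
p-values within nested secondary strata c ∈ {1, 0.1, 0.01, 0.001}. Because
genome-wide p-values are correlated through LD, F̂ is estimated on random
LD-pruned subsets — a variant is kept in one pruning draw when its random
priority is maximal within its r² > 0.1 neighborhood — and averaged over 10
seeded iterations. Strata with fewer than 100 pruned variants collapse into
their parent stratum. The CDF grid spans −log₁₀p ∈ [0, 12] in steps of 0.1
and is made monotone along the primary axis by a running maximum; lookups
interpolate log₁₀F̂ linearly in log₁₀p. A variant's condFDR is the minimum
over all strata whose cutoff its secondary p-value satisfies, which enforces
that tightening the conditioning stratum never increases the estimate, and
is capped at 1. The conjunctional FDR is the maximum of the two directional
condFDRs; conjFDR < 0.05 defines a pleiotropic variant.

Two genomic regions with extreme long-range LD — the extended MHC
(chr6:25–35 Mb) and the APOE region (chr19:45–46 Mb) — are excluded from
grid fitting by default (they remain scorable); both are configurable, and
the defaults are stamped into output metadata as assumptions.

Interpolating across the discrete strata (a full bilinear scheme) was
considered and rejected: the running-minimum over nested strata is simpler,
order-preserving, and testable against direct enumeration.

*Calibration truth.* In simulations the package scores a conjFDR discovery
as "true" when the variant shares a signal — LD r² at or above the clumping
independence threshold 0.01 — with causal variants of both traits. This is
deliberately the same threshold that defines independent signals downstream:
a variant inside a signal containing causals of both traits is a correct
pleiotropic call even if it is not itself causal.

## Tiered locus prioritization

Pleiotropic variants are greedily clumped: the unassigned variant with the
smallest conjFDR (ties: smaller primary p, then ID) leads a clump and
absorbs all unassigned variants with r² ≥ 0.01 to it. Clumps whose leads lie
within 250 kb and in LD are merged — the clumping definition needs a merging
rule for near-coincident leads, and 250 kb is the conventional locus radius.
Ranking by conjFDR rather than GWAS p reflects that clumps represent
pleiotropic signals, whose natural ordering statistic is the conjFDR.

The cascade: Tier 3 is every clump. Tier 2 requires a member variant with a
sex-biased outcome effect: two-sided heterogeneity
Z = (β_men − β_women)/√(SE²_men + SE²_women) at P < 0.05, or a fold ratio
max(|β_w|,|β_m|)/max(min(|β_w|,|β_m|), 10⁻⁸) above 1.5. Opposite-sign betas
(both nonzero) always count as sex-biased: the fold rule is undefined under
sign flips, and a sign reversal is the strongest form of sex difference. The
ratio and the sign condition are both reported so either convention can be
audited. Tier 1 additionally requires cross-trait colocalization PP4 ≥ 0.7
at the clump; a missing colocalization result caps the clump at Tier 2 with
a warning. The sex-bias direction is the sex with the larger |β| at the most
significant sex-biased member, and the output records whether the best
colocalizing variant (the top per-variant H4 contributor) itself passes the
sex-bias criterion — it need not.

Novelty: a Tier-1 lead is novel when no user-supplied known risk locus lies
on the same chromosome strictly within 1 Mb.

## Colocalization

Per-variant evidence is the Wakefield approximate Bayes factor
log ABF = ½[log(1−r) + r z²] with r = W/(SE² + W) and z = β/SE. Hypothesis
sums (H0 none; H1/H2 single-trait; H3 two distinct causal variants; H4 one
shared) combine per-variant ABFs with configuration priors p₁ = p₂ = 10⁻⁴,
p12 = 10⁻⁵ — the conventional defaults for this model family, surfaced in
configuration and logged. Effect-prior variances default to W = 0.15² for
case-control (log-OR) traits and 0.2² for quantitative traits. All
accumulation uses log-sum-exp, so regions with |z| > 40 are handled without
overflow; the H3 cross term is computed as exp-sum-minus-diagonal in log
space. The single-causal-variant formulation is implemented and labeled as
such; conditional/multi-causal extensions are out of scope. Variants missing
from either region are dropped, never imputed. PP4 ≥ 0.70 is reported as
"strong" colocalization, both for the Tier-1 gate and for QTL scans, whose
results aggregate to the best PP4 per (feature, category) with the
contributing dataset recorded.

## Motif analysis

Promoter windows are −1000/+300 bp around the TSS, reflected on the minus
strand so "upstream" follows transcription. PWMs carry a pseudocount of 0.01
added to probabilities before the log₂ likelihood ratio against a uniform
background (both configurable). Scores scale to [0, 1] as the fraction of
each motif's possible score range — per motif, not per sequence — and
matches at scaled score ≥ 0.85 are retained. Both strands are scanned;
windows containing N are skipped. A single-nucleotide variant's motif
disruption is the difference between the best overlapping scaled scores of
the alternate and reference alleles, retained when either allele reaches the
threshold. Set-level enrichment is the one-sided hypergeometric tail on
promoter counts (a promoter "contains" a motif if it has ≥ 1 hit), filtered
at P < 0.05. De-novo motif discovery is not implemented: known-motif
scanning plus set enrichment preserves the decision-relevant output (is a
hormone-receptor-like motif over-represented in the sex-biased gene set,
with a p-value) without an EM motif optimizer. The built-in example PWM is a
synthetic steroid-receptor-like inverted repeat (AGAACAnnnTGTTCT) used by the
simulator and the pipeline's motif stage.

## Mendelian randomization

Instruments: P < 5×10⁻⁸, then greedy p-ranked clumping at r² < 0.001.
Harmonization aligns outcome records to the exposure effect allele
(strand-complement matching before swap detection) and drops palindromic
instruments outright.

* **IVW (primary).** Weighted regression of β_out on β_exp through the
  origin, weights 1/SE²_out. Random effects enter as multiplicative
  overdispersion: SE × √max(Q/(k−1), 1) — the standard summary-data
  convention for a "random-effects model". One instrument reduces to the
  Wald ratio with the first-order delta SE (a second-order term is available
  behind a flag).
* **MR-Egger.** Instruments oriented to β_exp ≥ 0, weighted regression with
  intercept; the intercept and its p-value test directional pleiotropy;
  overdispersion scaling with k−2 df.
* **Weighted median / mode.** Inverse-variance weights on Wald ratios;
  median by interpolated weighted quantile, mode by the peak of a weighted
  Gaussian KDE with a MAD-based bandwidth times a configurable factor. SEs
  by seeded parametric bootstrap (default 5000 draws) of the ratio
  estimates.
* **Cochran Q** under IVW (df k−1) and Egger (df k−2); p omitted at df ≤ 0.
* **Leave-one-out.** IVW refits dropping each instrument; an instrument is
  flagged when its removal moves the estimate by more than one SE of the
  refit or flips nominal significance. The refit SE is used because an
  influential outlier inflates the full-model SE through the heterogeneity
  scaling, which would mask exactly the instruments the diagnostic exists to
  find.
* **Global pleiotropy test.** Observed statistic: standardized RSS of
  outcome betas about leave-one-out IVW predictions. Null distribution by
  parametric simulation with *both* sides resampled — β*_exp ~ N(β_exp,
  SE_exp) and β*_out ~ N(prediction, SE_out) — with fresh leave-one-out fits
  per draw (default 1000). Resampling only the outcome side leaves the
  observed residual variance (SE²_out + β²SE²_exp) unmatched and the test
  anticonservative; with both sides resampled the null p-value is uniform
  (verified by a 200-replicate Kolmogorov–Smirnov check).
* **Sample-overlap adjustment.** No named procedure exists for summary-data
  overlap inflation, so the package implements a parametric one and labels
  it in outputs: overlapping participants induce an error correlation
  c = overlap_fraction × min(nE,nO)/√(nE·nO) × phenotype correlation
  (default 0.2, configurable); each instrument's outcome variance gains
  2c|β̂|SE_exp·SE_out, inflating the SE monotonically in the overlap while
  leaving the point estimate unchanged.
* **Multivariable IVW.** Weighted multivariable regression without
  intercept; exposures whose instrument effects are all zero are dropped
  (reported as NaN) so the remaining estimates reduce exactly to the
  univariable fit; genuinely collinear exposures raise an error naming them.
* **BH-FDR.** Step-up adjustment per sex stratum; the family is all
  exposure–outcome tests supplied within one sex, and the family composition
  is echoed in the output.

## The simulator and what the tests show

Marginal z-scores follow z = √n·R·γ + ε with AR(1) block LD
(r[i,j] = ρ^|i−j|, blocks independent), spike-slab causal effects
(null/trait-A/trait-B/shared; shared variants use one common γ), per-trait
noise covariance R and cross-trait covariance (overlap)·R. Records sit on
the standardized scale: SE = 1/√n, β = z·SE. Defaults describe a
biobank-scale pair: 100k variants, blocks of 100, ρ = 0.6, n = 100k per
trait, 0.6% causal variants split evenly across the three causal classes,
effect SD 0.02 (≈ |z| 6 at a causal variant), no overlap. Sex-stratified
simulation adds per-sex Gaussian deviations (SD τ) at causal variants, with
designated blocks carrying an exact female:male fold ratio. QTL regions
plant single causal variants explaining a set variance fraction, giving
expected peak χ² = 1 + n·(variance explained). Promoters are i.i.d. uniform
sequence with the PWM consensus planted at a uniform position. The
study-level generator plants the five-locus fixture (two shared+sex-biased,
one shared, one sex-biased, one null, plus a few trait-specific background
loci) at block centers with target causal z-scores (male AD 7, hormone 9,
female:male fold 2) over ~20k background variants.

What this does *not* emulate: realistic MAF and LD spectra, genotyping or
imputation error, population stratification, winner's-curse selection of
instruments, binary-trait liability scale subtleties. Passing tests
establish that the estimators are correct and calibrated under their stated
models — not that real hormone–disease analyses are free of those
complications.

Problem sizes in tests and the acceptance script (20 genome-scale conjFDR
replicates, 200 colocalization regions and MR replicates, 300 inner draws
for the global test) are chosen so the whole suite completes in about a
minute on one CPU while keeping Monte-Carlo error well inside the asserted
margins.

## Numerical and degenerate-input conventions

p-values are floored at 10⁻³⁰⁰; empirical CDFs at 1/(stratum count).
Positions are 1-based; BED output 0-based half-open. Alleles are upper-cased
on read; indels pass through IO but are never strand-flipped or
motif-scored. The fold-ratio denominator is floored at 10⁻⁸. Ties in
clumping break deterministically (conjFDR, then p, then ID), making output
independent of input order. All generators take explicit seeds and never
touch global RNG state; rerunning any stage with the same configuration
reproduces outputs byte-identically.

## Known limitations

- The condFDR stratification is coarse below secondary p < 10⁻³; extremely
  strong conditioning evidence earns no further credit.
- Single-causal-variant colocalization mis-ranks regions with multiple
  causal variants per trait.
- LD is block-AR(1) throughout; methods accept arbitrary LD matrices for
  small regions, but genome-scale real LD panels are out of scope.
- The sample-overlap SE inflation is one defensible parametric choice, not
  a community-standard estimator; its assumptions are printed with every
  result.
- The variant IDs are opaque keys: no genome build is assumed, and no
  liftover is provided.
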