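# Methods

## The problem

Two-sample Mendelian randomization (MR) estimates the causal effect of an
exposure on an outcome from GWAS summary statistics alone, using genetic
variants as instruments: a variant that robustly shifts the exposure, is
independent of confounders, and affects the outcome only through the
exposure acts as a natural randomized assignment. `trimr` implements the
three-leg design used to probe whether gut-microbial taxa mediate the link
between inflammatory bowel disease (IBD) and its extraintestinal
manifestations (EIMs): (1) disease → EIMs, (2) disease → taxon abundances,
(3) taxon abundances → EIMs, followed by a product-of-coefficients
mediation decomposition for taxa significant on both legs.

## Generating model of the synthetic data

Real consortium GWAS downloads are out of scope; every stage is exercised
on synthetic summary statistics with known truth. For SNP j with true
instrument strength γ_j > 0, causal effect θ, and pleiotropic direct
effect α_j:

    γ̂_j = γ_j + ε_xj,              ε_xj ~ N(0, se_xj²)
    Γ̂_j = θ·γ_j + α_j + ε_yj,      ε_yj ~ N(0, se_yj²)
    se ≈ 1 / sqrt(2·maf_j·(1−maf_j)·n)

the standard linear summary-statistics model under which IVW, Egger and
the weighted median have their textbook behaviour. Standard errors derive
from allele frequency and sample size so that F-statistics respond to n as
in a real GWAS. Betas are interpreted as log-odds for binary traits, and
odds ratios are exp(β) throughout.

Defaults emulate the study conditions: exposure GWAS of 18,340
participants (the microbiome-GWAS meta-analysis scale), outcome GWAS of
65,642 (an IBD case/control consortium scale), maf ~ U(0.1, 0.5), and
instrument strengths |N(0.1, 0.04)|, truncated positive so effect alleles
are trait-increasing. The wide γ spread is deliberate: MR-Egger is only
approximately unbiased when instrument-strength heterogeneity is large
relative to the exposure-side noise (high I²_GX); with a narrow γ
distribution the Egger slope is attenuated by regression dilution no
matter how it is coded. Pleiotropy comes in three flavours — balanced
(α ~ N(0, τ²)), directional (mean μ ≠ 0), and InSIDE-violating
(α correlated with γ via a configurable ρ, default 0) — plus gross
outliers: a configurable fraction of SNPs receives |α| uniform in 10–15×
the balanced scale (falling back to 10–15× |θ|·mean γ, then to the median
outcome SE, when τ = 0). An `outcome_seed` lets one exposure GWAS drive
several independent outcomes, as when a single disease GWAS supplies the
instruments for every downstream trait.

What the generator does **not** emulate: liability-threshold case/control
sampling (outcome noise is Gaussian on the log-odds scale), realistic MAF
spectra or LD beyond constant-r² blocks, sample overlap between studies,
and population stratification. Passing tests therefore demonstrate
correctness of the estimators and filters under the linear model, not
robustness to those real-data pathologies.

## Instrument QC chain

p-value selection (strict p < 1e-5 for microbiota exposures, 5e-8 for
disease exposures) → greedy LD clumping (keep the most significant SNP,
drop neighbours with r² ≥ 0.001 within 10,000 kb, recurse; ties broken
lexicographically on SNP id for determinism; without positions only the r²
rule applies; SNPs absent from the LD matrix count as unlinked with a
warning) → weak-instrument filter (per-SNP F > 10, with
F = R²(n−k−1)/(k(1−R²)) at k = 1; joint-k scoring exposed separately) →
removal of palindromic A/T and C/G SNPs (dropped unconditionally, no
frequency-based rescue) → MAF filter (min(eaf, 1−eaf) < 0.01 excluded, on
the exposure side; records without eaf are kept with a warning) →
harmonization onto the exposure's effect allele (swapped alleles negate
the outcome beta; a strand flip is attempted before declaring a mismatch,
except for palindromic pairs where flips are indistinguishable; drops are
logged with reasons, never raised). Per-SNP variance explained uses the
regression-t identity R² = t²/(t² + n − 2), which needs no allele
frequency and is exact under the regression-t correspondence.

## Estimators

Per-SNP Wald ratios r_j = Γ̂_j/γ̂_j carry first-order delta-method SEs
se_out/|γ̂_j| (exposure-side uncertainty ignored, the convention of
standard two-sample MR tooling; a second-order SE is available behind a
flag). IVW is the inverse-variance-weighted mean of the ratios —
algebraically the weighted through-origin regression of outcome on
exposure betas with weights 1/se_out², an identity asserted in tests.
Cochran's Q = Σ w_j (r_j − β̂)² on k−1 df decides the model: random
effects (multiplicative overdispersion, SE × sqrt(max(1, Q/df));
additive DerSimonian–Laird is not implemented) when Q's p < 0.05, fixed
otherwise; both are always reported. MR-Egger is the weighted regression
with a free intercept after orienting exposure betas non-negative; slope
and intercept use a t reference on k−2 df. The weighted median sorts the
ratios, standardizes cumulative weights p_j = (cum w − w_j/2)/Σw, and
interpolates at 0.5; its SE comes from a seeded parametric bootstrap
(default 1000 resamples, normal around each ratio). Note the weighted
median's robustness to <50% invalid weight is asymptotic in instrument
strength: under one-sided contamination of weight fraction ε its bias is
the clean-ratio quantile shift F⁻¹(0.5/(1−ε)) − θ, which shrinks with
per-SNP noise, not with the number of replicates.

## Sensitivity battery

**MR-PRESSO.** The observed statistic is the weighted residual sum of
squares of the outcome betas around their leave-one-out IVW predictions
(SNP j predicted by the slope fitted without j, closed-form downdates).
The null distribution re-simulates both sides parametrically under the
fitted no-pleiotropy model n_sim times (default 1000) and recomputes the
same statistic; the global p is (1 + #{sim RSS ≥ obs})/(n_sim + 1), so it
is floored at 1/(n_sim+1). Per-SNP outlier p-values compare each SNP's
weighted squared residual to its own simulated distribution,
Bonferroni-tested at 0.05/k — when k is large the Bonferroni threshold can
fall below the p floor, in which case n_sim must be raised for the outlier
test to have any power. When outliers are found, the distortion test
compares the pre/post-removal IVW change against removals of 1000 random
same-size SNP subsets (seeded).

**Leave-one-out.** Auto-model IVW excluding each SNP in turn; an
association is "dominated" iff it is nominally significant overall and
some single exclusion lifts its p above 0.05 or flips the sign — a
codification of the narrative screening criterion.

**Steiger directionality.** Instrument variance explained is summed per
side with the same t²/(t²+n−2) estimator; the implied correlations
sqrt(R²) are compared by a two-sample Fisher-z test. Direction is
"correct" when the exposure side strictly dominates; exact ties are
flagged ambiguous with p = 1.

## Classification and multiplicity

Per-rank Bonferroni thresholds are 0.05/m with m the number of taxa tested
at that rank, computed from the taxonomy actually analysed (reference
panel counts: genus 131, family 35, order 20, class 16, phylum 9). The
computed phylum threshold is 0.05/9 = 5.56e-3; a commonly printed 5.5e-3
is a truncation and is not reproduced. Associations are classified
**nominal** (IVW p < 0.05), **stable** (nominal + Egger intercept p >
0.05 + PRESSO global clean or corrected-estimate concordant with
distortion p ≥ 0.05 + not LOO-dominated + Steiger direction correct) and
**strong** (stable + IVW p below the rank threshold). "Stable" is an
interpretation codified from narrative usage rather than a formal
definition, and is deliberately conservative: the classes are nested by
construction. Pairs with no surviving instruments are reported with
classification "none" and reason `no_instruments`.

## Mediation

For a mediator significant on both legs, the mediated effect is
β_i = β₁·β₂/β_total from the auto-model IVW betas of each leg (selectable
by flag). The `consistent` flag marks whether sign(β₁·β₂) matches
sign(β_total); a sign-inconsistent triangle (mediated path opposing the
total effect) is reported but flagged as not a coherent mediation. No CI
for β_i is computed (out of scope).

## Numerical and reproducibility choices

Two-sided p-values use the standard normal reference (t on k−2 df for
Egger); p-values are clamped to (tiny, 1]. Every stochastic component
(simulation, bootstrap, PRESSO, distortion) takes an explicit seed;
grid runs spawn per-pair seeds from one master `SeedSequence`, making the
full pipeline a pure function of (inputs, config, seed) — byte-identical
reports on repeated runs are asserted in tests. Degenerate inputs are
handled explicitly: single-SNP sets reduce IVW to the Wald ratio with Q
undefined; Egger and the weighted median require ≥ 3 SNPs, PRESSO ≥ 4;
zero exposure betas are hard errors for ratios.

## Problem sizes used in the test suite

Monte-Carlo suites run at the sizes the analyses are designed for:
parameter recovery at 500 replicates of 150 SNPs with n = 50,000 per side;
type-I error at 100 null grid pairs and 200 PRESSO replicates at
n_sim = 1000; detection rates at 100 replicates. The robustness and
intercept-centring property tests run at n = 500,000 where the asymptotic
regime (negligible weak-instrument dilution) is the property under test.

## Known limitations

Wald-ratio SEs ignore exposure-side noise, so with a non-null θ Cochran's
Q is mildly anti-conservative and the auto rule drifts toward the
random-effects model — visible in the simulations and consistent with how
the standard tooling behaves. No proxy-SNP lookup, no reference-panel LD
estimation, no multivariable MR or mediation CIs. The LD model is
constant-r² blocks, sufficient for testing the clumping rule but not a
realistic haplotype structure.
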