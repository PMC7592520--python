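# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the points where the design was genuinely open.

## Association model and meta-analysis

Single-variant association is the standard dosage model: for variant *j*,
`trait ~ dosage_j + covariates`, ordinary least squares for quantitative
traits and logistic regression for binary ones, reporting the Wald β, SE and
two-sided *p* for the dosage term against the normal reference (no
small-sample *t* correction). The linear path is vectorised across variants
by Frisch–Waugh–Lovell: the covariate block is QR-factorised once, the trait
and all dosage columns are residualised against it, and each per-variant
slope is the one-dimensional regression of residual on residual — exactly
equal to the full multiple regression, at a cost of one matrix product per
GWAS. The logistic path is per-variant iteratively reweighted least squares
(max 50 iterations, step tolerance 1e−8); non-convergence or separation
yields a missing record, as do monomorphic variants. Missing dosages are
mean-imputed per variant, samples with missing traits are dropped.

Strata are pooled by DerSimonian–Laird random-effects meta-analysis:
fixed weights w = 1/se², Q = Σw(β−β_FE)²,
τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)), random weights
w\* = 1/(se² + τ²). Whenever Q ≤ k−1 the moment estimate is zero and the
pooled result equals the fixed-effects result; with one stratum the input is
returned unchanged. DL was chosen as the estimator because it is the
closed-form historical default of meta-analysis software and is verifiable
by hand arithmetic in tests.

Genomic inflation is summarised as λ = median(χ²)/0.4549 and no genomic
control correction is applied anywhere.

## Allele harmonization

Sources are matched on chrom:pos. Swapped alleles flip the β sign and
complement the frequency; strand flips are resolved by base complement;
palindromic A/T and C/G variants are unresolvable when the frequency is
uninformative, so those with EAF in (0.4, 0.6) are dropped and counted,
while outside that band the minor/major orientation decides. Anything else
is irreconcilable and dropped. The operation is idempotent.

## Cohort-specific discovery

The specificity rule requires all three of: cohort *p* < 0.01, reference
*p* ≥ 0.05, and disjoint 99% confidence intervals β ± 2.5758293·se.
Intervals sharing even an endpoint count as overlapping — the conservative
reading. The two sources must be on comparable scales before the interval
comparison; all traits in this package are unit-variance and β is
per-dosage on both sides, which satisfies that requirement by construction.
Variants absent from the reference are recorded as not callable rather than
specific. Clumping into independent loci is greedy by ascending cohort *p*
(ties broken by position, then variant id); a call joins a locus only when
it is both within the window (500 kb default) of the index variant and in
LD with it (r² > 0.5 default).

Gene-set overrepresentation is the one-sided Fisher exact test of hit genes
against each GMT set restricted to the analysis universe, BH-adjusted across
sets; depletion is deliberately not flagged. The eSNP enrichment pipeline
per condition excludes variants with reference *p* < 1e−6, LD-prunes the
survivors at r² > 0.2 (strict inequality, per its own convention), and
tests the 2×2 of eSNP proportion among specific vs remaining variants with
a 1-df χ² without continuity correction; when any expected cell is below 5
it falls back to Fisher's exact test and flags the row. BH-FDR is applied
across conditions. The BH step-up itself is implemented directly (sorted
p·m/rank with a reverse cumulative minimum) and cross-checked against
statsmodels in tests.

## Polygenic scores

Thresholding–pruning: keep variants with *p* strictly below the threshold
(grid 1e−1 … 1e−8), then greedily prune by ascending *p* (ties: position,
then id), removing any variant with r² ≥ 0.5 against an already-retained
one in the reference panel. Variants absent from the panel carry no LD
evidence and are retained with a warning. Scores are Σ dosage × β with the
effect allele matched to the panel ALT (swapped alleles reflect the dosage);
missing dosages are mean-imputed as 2·EAF from the model record, matching
common scoring-tool behaviour and keeping scores comparable across samples;
more than 20% unmappable model variants is an error.

Multiethnic mixing: the phenotype is regressed on both scores plus
covariates; α₁ and α₂ are the two score coefficients, unconstrained in sign.
Performance is the incremental R² of the scores over the covariate-only
model, adjusted as 1 − (1−R²)(n−1)/(n−k−1) with **k the number of score
terms (2, or 1 in the collinear fallback)** — the covariates appear in both
the full and baseline models and cancel from the increment, so penalising
them again would conflate covariate dimensionality with score skill. Scores
correlated above |r| = 0.999 trigger a flagged fallback to the
reference-only model with α₂ undefined.

Cross-validation re-estimates the target-stratum GWAS on each 90% training
split (ten folds; case/control-stratified for binary traits, each fold's
case count within one of the global ratio), derives target-stratum weights
at the working threshold, and evaluates mixing weights and incremental
adjusted R² on the held-out 10%. PCs enter the fold GWAS covariates and are
computed once on the full target stratum. The reference-only adjusted R² is
recorded per fold as the comparison baseline.

Risk stratification uses the raw 2×2 prevalence comparison: the top group is
every sample at or above the empirical (1−q) quantile of the score (ties
included, so the group can slightly exceed q·n), OR = (a·d)/(b·c), Wald 95%
CI on the log odds with the Haldane–Anscombe 0.5 correction (flagged) when
any cell is empty, and BH-FDR across all score × fraction rows per disease.
A covariate-adjusted logistic alternative was considered and set aside: the
quantity of interest is the prevalence contrast itself, and the unadjusted
table keeps the estimate interpretable as such.

The pooled PRS R² across strata is the inverse-variance fixed-effects pool
of the per-stratum standardized marginal coefficients, squared.

## Phenotype derivations

LDL per draw prefers the direct measurement and otherwise applies the
Friedewald equation LDL = TC − HDL − TG/5, declared invalid (missing) above
TG = 400 mg/dL — the standard validity bound of the equation. Per-sample
lipids are arithmetic means over all resolvable draws. Statin exclusion
removes samples with a lipid-lowering medication at baseline — defined as
the earliest medication record day per sample — from lipid analyses only.
T2D is adjudicated positive on any of: HbA1c ≥ 6.5 ever, a
diabetes-specific medication ever, or a diabetes-related medication together
with a diagnosis flag; absent data sources are negative evidence. The
baseline table reports count (percent of stratum n, one decimal) with χ²
for categorical variables and mean ± SD with the unequal-variance
(Welch–Satterthwaite) t-test for continuous ones; Welch was chosen because
it reproduces the published-style p-values recomputed from summary rows
where the pooled-variance test does not, and it is computable from
summaries alone.

## Quality control

Filters run in a fixed order — variant call rate, MAF, HWE; sample call
rate, sex concordance, relatedness — and each removal is attributed to the
first failing filter, so report counts reconcile exactly. All thresholds are
strict inequalities (boundary values kept). HWE and identity-by-state are
defined on genotypes, not dosage expectations, so dosages are hard-called at
the nearest integer when within 0.1, missing otherwise; HWE is the exact
conditional test on the heterozygote count (probabilities summed over
configurations no more likely than observed) and is tested within each
ancestry stratum, since pooling diverged strata manufactures heterozygote
deficits (Wahlund effect) that are not genotyping error. Relatedness is the
method-of-moments IBD estimate from IBS counts under sample allele
frequencies, π̂ = P(IBD=1)/2 + P(IBD=2) clipped to [0,1], computed on
variants with complete calls; fewer than 50 usable variants flags the
estimates low-confidence. Of a pair with π̂ > 0.9 the member with the lower
call rate is removed, ties going to the lexicographically larger id. PCA
standardizes each variant by √(2f(1−f)) after centering at 2f, drops an
optional exclusion interval (an MHC analogue; default none for synthetic
data) and monomorphic variants, and fixes signs by making the
largest-magnitude loading of each component positive.

## The synthetic generator

Genotypes: each stratum's allele frequencies are Balding–Nichols draws
Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral frequency drawn uniformly
from the configured range, clipped into the stratum's interval (F = 0.05 by
default, a typical European–African autosomal divergence). LD is generated
per block from a latent exchangeable Gaussian: each individual receives two
gametes, each gamete one shared factor plus independent noise, thresholded
at the frequency quantile of each variant. The latent correlation ρ is
calibrated per block and stratum by solving for the value at which the mean
pairwise squared indicator correlation — computed at the block's actual
frequencies via the bivariate normal CDF — equals the requested r² (the
heterogeneity of frequencies caps the achievable r²; the solution saturates
at that cap). Dosages are therefore exact genotypes in {0,1,2}; Hardy–
Weinberg holds within stratum by construction.

Phenotypes: causal effects for the two strata are drawn jointly with
correlation `ancestry_effect_corr`; the genetic value is standardized within
stratum so h² is the stratum-wise genetic variance share; the trait is
√h²·g + covariate terms + √(1−h²)·ε. Binary traits threshold that liability
at its empirical mean + SD·Φ⁻¹(1−prevalence). Default demographics mirror a
predominantly male HIV clinical cohort (male fraction 0.893/0.690 by
stratum, ART exposure 0.918/0.885, age 53 ± 10, four sites); four sites
rather than eight keep the site indicator block well-conditioned at small
simulated n.

Reference summary statistics: the true per-dosage marginal effect of each
variant on the unit-variance trait is computed in closed form from the
block-LD model (pairwise indicator correlations within causal blocks, zero
across blocks), and the estimate is drawn around it with the exact standard
error 1/√(2f(1−f)·n_ref). Null variants therefore have exactly uniform
p-values, and the generator reproduces the textbook SE (e.g. 0.00632 at
f = 0.5, n = 50 000).

Clinical records are constructed to be consistent with the derivation rules:
repeated lipid panels scatter around each sample's target with the total
cholesterol back-computed so the Friedewald-resolved LDL recovers the
target; T2D-positive samples satisfy exactly one randomly chosen
adjudication criterion and negatives none; a configurable fraction receives
a baseline statin record and is therefore removed by the exclusion rule.

What the generator does **not** emulate: haplotype-level LD decay and
recombination maps, admixture tracts, imputation uncertainty (dosages are
exact), genotyping batch effects, site- or calendar-time-structured
phenotype drift, and medication histories beyond the minimal codes the
adjudication rules read. Passing tests therefore demonstrate the internal
correctness and calibration of the statistical machinery under the stated
generative model, not performance on real cohort data.

## Problem sizes and tolerances

The test and acceptance workloads are sized to what the statistics need
rather than more: null calibration uses 2 000 samples × 2 000–5 000
variants (binomial SE of the type-I rate ≈ 0.005 at the 0.05 level);
specificity error rates use 3 000 samples, 300 variants, MAF 0.3, reference
n = 100 000 (per-variant power at β = 0.5 is effectively 1, so sensitivity
is governed by the reference-null 0.95 pass rate and the CI criterion); the
multiethnic cross-validation comparison uses 1 500 target-stratum samples,
300 variants, 50 causals, h² = 0.4, effect correlation 0.3, over ten
generator seeds. Oracle-equivalence checks run at ≤ 20-element instances
with tolerances 1e−9–1e−12; recovery checks use the binomial/normal
concentration bounds stated in their assertions.

## Known limitations

* Relatedness estimation uses complete-call variants only and omits the
  finite-sample allele-frequency corrections of the classic
  method-of-moments estimator; with the ≥ 50-variant guard this is accurate
  for the π̂ > 0.9 duplicate screen it serves, but π̂ for distant relatives
  is noisier than specialised tools report.
* The sex-concordance check is an X-heterozygosity proxy over caller-designated
  markers and is skipped when none are supplied (the synthetic genome is
  autosomal).
* The logistic path is fitted per variant and is correspondingly slower
  than the vectorised linear path; genome-wide binary-trait cross-validation
  at large variant counts is the package's slowest operation.
* Greedy LD pruning and clumping are order-dependent by design (ascending
  p); they are not guaranteed to find a maximum independent set.
* The eQTL enrichment treats eSNP flags as exchangeable annotations; it
  does not model LD between the specific and remaining groups beyond the
  pruning step.
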