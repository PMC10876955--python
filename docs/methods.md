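# Methods

This note records the statistical models implemented in `postgwas`, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical decisions a maintainer would want written
down.

## Summary-statistic model and harmonisation

A variant record carries (effect allele, other allele, EAF, β, SE, Z, p, N)
with β in trait-SD units per effect-allele copy (log-odds for binary traits)
and 1-based positions. Harmonisation aligns a second study to the first's
allele coding: swapped alleles flip the signs of β and Z and complement the
EAF. Palindromic variants (A/T, C/G) cannot be strand-resolved from alleles
alone; they are kept only when both studies' EAFs are informative, i.e.
min(EAF, 1−EAF) ≤ 0.42, and dropped when either EAF is missing or inside
that window. The 0.42 cut-off is the conservative end of common practice;
it is a module constant rather than a tuned value.

Two-sided p-values are computed through the normal survival function (and a
log-space variant for |Z| beyond the double underflow point), and emitted in
3-significant-figure scientific notation to mirror how GWAS tables print
them; internal precision is full floating point.

## Summary-statistic imputation

Unobserved variants' Z-scores are imputed under the standard multivariate-
normal model for GWAS Z-statistics: with LD correlation matrix Σ,
`z_t = Σ_to (Σ_oo + λI)⁻¹ z_o` and imputation quality
`r²_t = Σ_to (Σ_oo + λI)⁻¹ Σ_ot`. The ridge λ defaults to 0.1 — the external
tools in this family never publish the value they use, so it is exposed as a
parameter — and observed variants are windowed to 250 kb around each target.
Targets with r² > 0.8 are flagged as confidently imputed, the conventional
retention rule. The implementation refuses a singular observed-observed
block at λ = 0 with a pointer to the ridge.

## Meta-analysis and locus definition

Stouffer's method combines Z-scores with √N weights when studies report
different units; the fixed-effects IVW estimator pools effect sizes directly
when all studies share trait-SD units. Variants carried by a single study
pass through flagged rather than silently meta-analysed; variants missing N
are excluded from Stouffer. Heterogeneity uses Cochran's Q about the pooled
estimate. Locus definition is greedy and p-ascending: independent
significant variants at pairwise r² ≤ 0.6, lead variants among them at
r² ≤ 0.1, block intervals spanned by each independent variant's clumped
members, and blocks whose *edges* fall within 250 kb merged (the merge rule
measures gap between block boundaries, not between leads). The directional
replication test is the one-sided binomial P(X ≥ k | n, ½) on the count of
lead variants whose replication mean-Z shares the discovery sign.

The Cauchy combination (ACAT) aggregates rare-variant p-values to genes.
p = 1 is clipped to 1 − 1e-16 before the tangent transform; p below 1e-15
uses the asymptotic 1/(pπ) form of the transform, and a saturated statistic
returns the matching 1/(Tπ) tail so extremely small combined p-values stay
finite and ordered.

## Finemapping and colocalisation

Wakefield's approximate Bayes factor uses prior effect variance W = 0.15
everywhere, the conventional value for quantitative traits; it is
configurable per call (and per trait inside colocalisation, since case-
control traits enter on the log-odds scale where a different W may be
sensible). Finemapping assumes a single causal variant per region, so
posterior inclusion probabilities are ABFs normalised within the region and
no LD model is needed. The credible set is the smallest pip-descending
prefix reaching the target level; pip ties break by smaller p, then
lexicographic id. Colocalisation enumerates single-causal configurations
for two traits with prior per-variant probabilities p1 = p2 = 1e-4 and
p12 = 1e-5 (the published defaults of the tool family; recorded in the
result object). All sums run in log space; with one shared variant the
distinct-causal hypothesis has no configurations and its mass is set to 0
with a warning.

## Mendelian randomisation

All estimators consume harmonised per-instrument effect quadruples. The IVW
estimate is weighted least squares of outcome on exposure effects through
the origin with weights se_out⁻²; fixed effects report se = √V with the
residual variance pinned at 1, while multiplicative random effects scale by
σ̂ = √(Q/(k−1)) **without flooring at 1** — so MRE standard errors are
smaller than fixed-effects ones whenever the instruments are
under-dispersed. This no-floor convention is deliberate and matches how the
estimator behaves in the wild; a `floor_sigma` switch restores the floored
variant. Perfectly collinear ratios give σ̂ = 0; the MRE se is reported as 0
with a degeneracy flag rather than raising.

MR-Egger orients every instrument to a positive exposure effect, then fits
the same weighted regression with a free intercept; the intercept estimates
average directional pleiotropy and its SEs use the same multiplicative
convention (df = k−2). The weighted median interpolates the 50th percentile
over cumulative-weight midpoints with first-order ratio variances (the
second-order variant is a switch away, `postgwas.mr` keeps first-order as
the default since the choice is rarely material and first-order is what the
common implementations use). The weighted mode maximises an inverse-
variance-weighted Gaussian kernel density over the ratios with bandwidth
φ · 0.9 · min(sd, mad/0.6745) · k^(−1/5), φ = 1 by default, evaluated on a
512-point grid spanning the ratios ± 3 bandwidths. Median and mode standard
errors come from a seeded parametric bootstrap (default 1000 replicates;
`n_boot=0` skips the bootstrap for point-estimate-only simulation work).
Instrument diagnostics report per-instrument F = (β_exp/se_exp)², their
mean, and I²_GX = max(0, (Q_GX − (k−1))/Q_GX) on the |β_exp| with weights
se_exp⁻², the Egger-reliability statistic.

Multivariable MR fits the outcome effects on the instrument-by-exposure
matrix: IVW without intercept, Egger with an intercept after orienting to
the first exposure, a per-exposure weighted median of ratios computed after
partialling the other exposures out of both sides by WLS (a pragmatic
stand-in for the bootstrap quantile-regression published variants), and a
LASSO that places an L1 penalty on per-IV intercepts. The LASSO penalty
follows a heterogeneity stopping rule: λ descends a geometric grid from the
smallest value that zeroes all intercepts, and the first λ whose zero-
intercept ("valid") instrument set passes Cochran's Q at 0.05 is kept, with
IVW refit on that set. Conditional instrument strength per exposure is the
Sanderson-style Q form: the weighted residual sum of squares from
regressing that exposure's instrument effects on the other exposures',
divided by k − E + 1, which reduces to the mean univariable F when E = 1.

## Phenome-wide screening and tiering

Outcomes with at least 6 instruments are screened by IVW-MRE; BH-FDR is
applied across outcomes and survivors at q < 0.01 pass to three filters —
no nominal heterogeneity (Q p ≥ 0.05), no nominal Egger intercept
(p ≥ 0.05), and significance robust to dropping any single instrument
(max leave-one-out p < 0.05; the source pipeline never states its exact
cut-off, 0.05 is the natural operationalisation). Filter survivors are
tiered by the count of nominally significant estimators among IVW-MRE,
IVW-FE, Egger, weighted median, weighted mode: 5 → tier 1, 4 → tier 2,
3 → tier 3. All significance is two-sided, including the Egger intercept.
Manual post-hoc curation (ancestry, GWAS power, cohort-release exclusions)
is represented as a caller-supplied exclusion list, not automated.
Bidirectional checks run the full suite in both directions, fall back from
genome-wide to suggestive (1e-5) instrument selection for the reverse
direction, mark the reverse untestable below 3 instruments, and label
binary-exposure reverse fits as null-hypothesis tests only.

A calibration note: under the null the IVW-MRE statistic β/se is exactly
Student-t with k−1 degrees of freedom (the residual scale is estimated),
while the reported p-values use the normal tail, as is conventional for
these estimators. At phenome scale this matters in the extreme tail: with
1000 null outcomes and k = 30, the BH boundary sits near 1e-5, where the
t₂₉ tail is an order of magnitude heavier than the normal tail
(P(|t₂₉| > 4.42) ≈ 1.3e-4 against 1e-5), so roughly one null phenome in
seven acquires a spurious BH survivor — and a survivor of a null screen is
by construction so significant that the sensitivity filters rarely block
it from a tier. The null-phenome simulations in the test suite measure
this honestly (~86-93% of null phenomes are clean, depending on the seed
range) rather than switching to t-quantiles, which would change the
estimator contract.

## Polygenic scores

C+T clumping is greedy and p-ascending with r² > r2_max removal inside a
250 kb window (r2_max 0.001 in instrument-selection mode); one model per
threshold from {5e-8, 1e-5, 1e-3, 0.01, 0.05, 0.1, 0.5, 1}. The
posterior-weighted score multiplies each variant's effect by its
single-causal PIP within caller-supplied independent LD blocks; a
per-variant prior-variance mapping supports heritability-derived priors.
Scoring is additive over dosages; missing dosages are mean-imputed at
2·EAF when the model carries frequencies (the common scoring-tool default),
otherwise dropped for that individual. Evaluation reports the test-split
ΔR² between covariate-only and covariate+score linear models under a
seeded 70/30 split; the related-sample mixed-model variant is out of scope
and the unrelated-split fixed-effects evaluation stands in for it.

## Empirical-Bayes polygenicity

Observed effects are modelled as β̂ᵢ ~ N(bᵢ, seᵢ²) with prior
b ~ π₀δ₀ + Σₖ πₖ N(0, σₖ²), the adaptive-shrinkage family restricted to
normal components (sufficient for the symmetric-unimodal use made of it,
and keeps EM closed-form). The SD ladder runs geometrically from
min(se)/10 to 2·max|β̂| with ratio √2 and is recorded in the fit. EM
maximises the marginal likelihood plus the standard null-biased penalty of
λ = 10 pseudo-counts on π₀, which resolves the near-flat likelihood between
the point mass and vanishingly small normal components in favour of the
null and makes 1 − π₀ conservative under the null — the property the
binned analysis depends on. The penalty has one visible cost: a *single*
overwhelming observation cannot push π₀ below (λ−1)/λ, because nine
pseudo-observations outvote it; `null_penalty=1` gives pure maximum
likelihood when that behaviour is wanted. Convergence is declared at a
log-likelihood gain below 1e-8 or 5000 iterations; the (penalised)
objective is asserted non-decreasing every iteration. Binned analysis uses
equal-count quantile bins of LD score, merges bins under 20 variants into
their neighbour, and smooths the per-bin fractions over bin rank with a
tricube local-linear smoother (standing in for an additive-model trend
line, and labelled as such in outputs).

## Normative centile model

The biomarker at age t follows a location-scale family with
μ(t) = b₀ + b₁·fp(t) + batch offsets and log σ(t) = c₀ + c₁·fp(t), where fp
is a first-order fractional polynomial with exponent searched over
{−2, −1, −0.5, 0, 0.5, 1, 2, 3} (0 = log). Families: Gaussian, and a
Box-Cox (Cole–Green) form z = ((y/μ)^ν − 1)/(νσ) ~ N(0,1) that captures
skew; the Box-Cox *t* family's extra tail parameter is omitted — the
deviation thresholds at the 5th/95th centiles are insensitive to mild tail
misfit, and the likelihood stays tractable. Family and exponent are chosen
by minimum BIC (AIC reported). Batch enters the location only; the scale
model is age-only. Fits are maximum likelihood (BFGS for Gaussian,
Nelder-Mead for Box-Cox) warm-started from OLS for μ and a log-|residual|
regression for log σ (shifted by −E[log|N(0,1)|] ≈ 0.635). Centile curves
are conditional quantiles of a monotone map, so they cannot cross.
Deviation calls use strict inequalities at 0.05/0.95; the split-half
protocol fits on a random participant half, calls the other, and swaps, so
every participant is called once per visit from a model they did not
train. The deviation-score association is one binomial logistic regression
per class (class vs all others) per visit on the standardised score, with
Wald 95% CIs; classes under 10 events fall back to a small-ridge penalised
fit and are flagged.

## Synthetic data

Generators are pure functions of a config whose master seed is combined
with a stable hash of the operation name, so repeated calls are
bit-identical and operations never share a stream. LD is block-diagonal
with AR(1)-style within-block decay (positive-definite by construction).
The two-cohort GWAS pair shares point-normal true effects (defaults:
non-null fraction 0.02; effect SD 0.05 trait-SD units, of the order of the
published lead-variant effects 0.066–0.172; cohort sizes 10,000/7,000,
two-cohort metabolite-GWAS scale) and draws each cohort's observed effects
from N(Rb, R/n) per block. Instrument sets plant a true causal effect
(default 0.15) with pleiotropy none/balanced/directional/correlated — the
correlated mode ties the direct effect to instrument strength,
violating InSIDE. The biomarker generator produces three visits spaced
about seven years apart (the layout of a longitudinal twin-registry
metabolomics panel) from a known location-scale law with batch offsets,
recording each row's true centile; the genotype generator draws
Hardy-Weinberg dosages and scales the genetic value to a target phenotypic
R² (default 0.02, matching the ~2% ΔR² regime the evaluation is meant to
detect). Not emulated: realistic human LD maps, imputation error,
relatedness/twin structure, sample overlap between exposure and outcome
GWAS, and winner's-curse selection of instruments — so passing recovery
tests demonstrate estimator correctness under each model's own
assumptions, not robustness to those real-data complications.

## Problem sizes

The acceptance-style simulations use: 500 instrument-set replicates for
estimator recovery; 100 phenomes × 1000 outcomes for null tiering
calibration; 2000 single-causal regions for credible-set coverage; 100/200
replicates for EB recovery/null calibration (n = 2000/5000 variants); 500
split-half simulations of 800 participants and 500 logistic-coverage
replicates for the normative model. `scripts/acceptance.py` uses the same
designs with 60 phenomes, 60/100 EB replicates and 200/300 normative
replicates, sizes chosen to keep a single-CPU run comfortably interactive
while leaving Monte-Carlo error well inside each quantity's decision
margin.
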