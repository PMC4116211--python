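# Methods

## The problem

Habitual caffeine consumption is heritable, and two common variants — the T
alleles of rs2472297 (between *CYP1A1* and *CYP1A2* on chromosome 15) and
rs6968865 (upstream of *AHR* on chromosome 7) — each raise intake by roughly
0.2 cups per day per allele. `caffscore` implements the analysis pipeline
that turns longitudinal food-frequency-questionnaire records and genotypes
at these two loci into (a) a refined caffeine-exposure phenotype, (b)
per-time-point additive association estimates and variance explained, and
(c) the validation evidence needed before the 2-SNP allelic score can serve
as an instrument in Mendelian randomization: balance against measured
confounders and null association with decaffeinated-drink negative
controls.

## Phenotype refinement

Questionnaire streams are harmonized to drinks/day per beverage:

* coffee and tea are reported per weekday and per weekend day; they are
  combined with the day-weighted mean `(5*wd + 2*we)/7`. No other convex
  combination yields "drinks per day" with correct units, but the specific
  weighting is our convention; equal-weight averaging changes values by at
  most 3/14 of the weekday-weekend gap.
* cola is reported per week — numerically at the pregnancy and 2-month
  waves, and as one of five closed frequency categories later. Categories
  are recoded to {0, 0.5, 2, 5.5, 7} drinks/week first and then divided by
  7, in that order.
* daily values above a per-beverage ceiling (10 coffee / 15 tea / 21 cola
  drinks per day) are set to missing. The rule is strict (`>`), so
  exactly-ceiling values survive, and it is applied to the *derived daily*
  values, after format conversion.

Total exposure is the caffeine-content-weighted sum
`75*coffee + 40*tea + 34.5*cola` mg/day. The total is complete-case: it is
missing whenever any caffeinated component is missing, which is what makes
per-time-point sample sizes vary. An `impute_zero_cola` option instead
treats missing cola as zero, as a sensitivity analysis only. Decaffeinated
streams are harmonized identically but held apart; they never enter the
total.

## Genotypes, QC and the allelic score

Genotypes are effect-allele (T) dosages in [0, 2]; analysis uses best-guess
hard calls with half-open rounding bins [0, 0.5) → 0, [0.5, 1.5) → 1,
[1.5, 2] → 2. Variant QC keeps a variant iff MAF ≥ 0.01, call rate ≥ 0.95
and the exact Hardy-Weinberg p-value exceeds 5×10⁻⁶; individuals with more
than 5% missing genotypes are removed *before* variant metrics are
computed, and every failed criterion is reported rather than
short-circuited. The effect allele is T at both loci (the major allele at
rs6968865, frequency 0.61); input readers refuse to flip alleles silently —
a column or VCF record counting a different allele is an error.

The Hardy-Weinberg test is the standard two-sided exact test: conditional
on the observed allele counts, every attainable heterozygote count is
enumerated, each configuration weighted by its multinomial multiplicity
(`2^h * n! / (n_minor_hom! h! n_major_hom!)`), and the p-value is the summed
probability of configurations no more probable than the observed one. No
mid-p correction is applied. Weights are computed with log-gamma functions
and normalized, which is exact to float precision for any realistic sample;
the test suite verifies bit-level agreement with an exact rational
enumeration for all configurations with up to 20 alleles and 10% relative
agreement with the 1-df chi-square approximation at n = 10,000.

The combined score is the per-subject T-allele count summed across loci
(0–4), missing if either genotype is missing. A weighted variant (0.31 per
rs2472297 allele, 0.26 per rs6968865 allele, the published per-allele
effects) is available; with unit weights it reduces exactly to the
unweighted score.

## Association models

Each phenotype × time point × predictor cell is a simple OLS of phenotype
on allele count with per-cell complete cases: slope, SE from the residual
variance, two-sided p from the t distribution with n − k degrees of freedom
(at these sample sizes the normal approximation would be
indistinguishable, but the convention is fixed), and R² as the squared
sample correlation. No multiple-testing adjustment is applied anywhere; the
eight time points are reported raw. Variance explained can also be computed
analytically as `beta² * var(score) / var(phenotype)`, with
`var(score) = 2q(1−q)` for a single SNP under Hardy-Weinberg; for simple
regression at the fitted beta with empirical variances this is an identity
with R².

Non-additivity is assessed with two auxiliary regressions: a within-locus
(dominance) model adding a heterozygote indicator to the allele count, and
a between-locus (epistasis) model adding the genotype product to both
counts. The reported quantity is each auxiliary term's estimate, SE and
two-sided t p-value. Numerically perfect fits (noiseless inputs) are
detected by residual variance relative to the response scale and resolved
to p = 1 for a null term and p → 0 for a non-zero term.

The regression core is closed-form numpy rather than a statsmodels call
because the calibration studies fit thousands of replicates; statsmodels is
retained as the independent cross-check in the test suite (coefficients,
SEs and p-values agree to 1e-9 relative).

A sensitivity sweep restricted to subjects reporting strictly positive
consumption of the analysed beverage mirrors the primary sweep through the
same code path.

## Instrument validation

Confounder balance regresses each confounder (year of birth, housing
tenure, crowding index, education level, alcohol drinks/week, tobacco
times/day) on each genetic predictor, one at a time; ordinal codings are
treated as numeric (linearity imposed), matching the marginal, single-
confounder layout of the published tables. The observational counterpart
regresses total caffeine on each confounder per time point. Decaf negative
controls reuse the association sweep verbatim on the decaffeinated columns
and annotate each cell with a `consistent_with_null` flag (two-sided
p > 0.05, uncorrected) — a report annotation, not an inferential claim.

## Synthetic cohort generator

The generator exists because the underlying cohort data are managed-access;
it emulates the *statistical structure the analysis assumes*, parameterized
by the packaged per-time-point constants (per-phenotype N, mean, SD and
per-T-allele coefficients):

* **Genotypes**: Hardy-Weinberg hard calls at T frequencies 0.27 and 0.61;
  optionally dosage noise scaled so corr²(dosage, call) matches a target
  imputation quality (0.96 for rs6968865), clipped to [0, 2]. Clipping
  trims tail noise, so the achieved quality sits slightly above nominal
  (≈0.97 for a 0.96 target); the hard calls used downstream are unaffected.
* **Consumption**: per beverage and time point, the latent value is
  `mu_adj + beta1*g1 + beta2*g2 + eps` with `eps` normal and `mu_adj`,
  `sd(eps)` calibrated so the *marginal* mean and SD equal the configured
  values. Effects are injected per-SNP (the additive generating model), so
  a combined-score regression targets the average of the per-SNP effects;
  scenarios aimed at the combined coefficient inject it equally at both
  loci. Cola carries no genotype effect, and decaffeinated streams none,
  matching the pattern the validation stage is meant to detect.
* **Noise model**: untruncated normal by default so OLS recovery targets
  are exactly unbiased; a left-censored option exists for realism (real
  consumption has a point mass at zero and right skew). Rendering into
  questionnaire form necessarily clamps negative latents at zero — counts
  cannot be negative and the refinement schema rejects them — so observed
  marginal means of a rendered cohort sit above the configured latent
  means. The truth table records both the latent and the rendered value,
  with the rendered value also reflecting the deterministic outlier mask,
  and the round-trip guarantee is defined against the rendered values.
* **Render**: coffee/tea are split into equal weekday/weekend counts (an
  information-free split that still exercises the 5/7–2/7 combiner); cola
  becomes a weekly count, discretized at the later waves to the nearest
  closed-category recode value with ties toward the smaller category.
  Configured missingness (default 5% per observation) and optional outlier
  injection are applied last.
* **Confounders** are built from the standardized *non-genetic* residual of
  18-week total caffeine (the published alcohol/tobacco measures are the
  18-week ones): each confounder's latent is `gamma*z + e` with fresh unit
  noise, so genotype ⟂ confounder holds exactly by construction and
  confounder-balance calibration is nominal for every effect size.
  Continuous confounders are affine in the latent and untruncated (linear
  recovery is then exact; the implied phenotype-on-confounder slope is
  `gamma*sigma_resid/(scale*(gamma²+1))`); housing tenure and education are
  quantile-thresholded ordinals; crowding is floored at a small positive
  value. Default gammas follow the observational sign pattern (renting,
  crowding, alcohol and tobacco up; education down; year of birth near
  null). The published confounding *magnitudes* are cohort-specific and are
  not targeted.
* **Seeding**: one master seed; each table (genotypes, consumption, decaf,
  confounders, missingness, outliers) draws from its own labelled
  substream, so adding or reconfiguring one table never perturbs the
  others, and identical configurations produce byte-identical TSVs.

What passing tests on this generator do *not* show: robustness to the right
skew, zero inflation, reporting error and beverage-level correlations of
real questionnaire data (the generator's beverages are conditionally
independent given genotype, so a rendered cohort's *total*-caffeine SD
exceeds the configured row SD even though each beverage matches its own).

## Calibration studies and problem sizes

Parameter recovery simulates replicate cohorts at a reference row's
parameterization and compares the replicate mean of the fitted coefficient
with the generating value on the Monte-Carlo SE scale. The shipped studies
use 200 replicates at the row's analysed N (4,460 for 145-month total
caffeine; 4,632 for tea), which puts the Monte-Carlo SE of the mean
coefficient near 0.16 mg (total) and 0.003 cups (tea). Null-calibration
studies use 1,000 replicates of modest cohorts (n = 250–400), sized so the
binomial 95% band around the nominal 5% rejection rate is ±1.4 points.
Genotype-marginal checks use n = 100,000 draws. All studies derive
per-replicate generators from `(seed, stream, replicate)` seed sequences
and are fully deterministic given the seed.

## Known limitations

* The generator is normal-theory throughout; none of the published
  skewness (distribution figures exist but print no parameters) is
  reproduced.
* Real weekday/weekend reporting contains information the equal-split
  render deliberately discards; the 5/7–2/7 combiner is therefore exercised
  but not stress-tested against asymmetric reports.
* Confounder magnitudes, the year-of-birth age structure, and
  between-confounder correlations beyond the shared phenotype residual are
  schematic.
* The pipeline stops at instrument validation: no causal (MR) effect
  estimation on outcomes, no genome-wide QC (relatedness, ancestry,
  imputation itself), and no genome-wide variance decomposition.
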