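# Methods

This note documents the statistical procedures implemented in `uratepath`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Study design being modelled

A candidate-pathway association study: nine biallelic SNPs, one per gene,
in two overlapping Gene Ontology molecular-function sets (GO:0015075 and
GO:0015291, eight genes each, seven shared; *PKD2* only in the former,
*SLC16A9* only in the latter). Phenotypes are serum urate (µmol/L,
quantitative), hyperuricemia (urate > 417 µmol/L, the monosodium-urate
saturation point), and clinically diagnosed gout. Analyses are stratified:
all samples / males / females for every contrast, plus WHO BMI bins
(< 18.5 / 18.5–25 / ≥ 25 kg/m²) for the urate contrast only. Genotypes are
hard calls (0/1/2 effect-allele counts); missing calls are excluded
pairwise per test and the exclusion is visible in each result's `n_used`.

## Per-SNP tests

**Urate (deviance analysis).** `urate ~ dosage + age (+ sex)` by OLS; the
SNP P-value is the nested-model F-test on the residual-sum-of-squares
reduction with 1 numerator df. For a single coefficient this is
algebraically identical to the squared-t Wald test (a unit test asserts
the identity to 1e-10); the F form is exact under Gaussian residuals,
which is why it is used rather than the asymptotic chi-square deviance.
The sex covariate is dropped automatically in single-sex strata; age is
always retained. A constant covariate or otherwise rank-deficient design
is a hard error naming the collinear column, and a SNP with no dosage
variance in a stratum is reported as `monomorphic`, not silently skipped.

**Case-control (allelic Fisher test).** "Additive-model" exact testing is
implemented as the 2×2 *allele-count* table: each subject contributes two
alleles (effect vs other), cases vs the comparison group. This is the only
reading under which a single odds ratio per SNP with a designated effect
allele is well defined; a Cochran–Armitage genotype-trend test is provided
behind a flag for users who prefer not to assume allelic independence
(which the allele-count table implicitly does under HWE). The two-sided P
follows the minimum-likelihood convention (sum of hypergeometric outcomes
with point probability ≤ observed) — the dominant convention in
statistical software, and the one our enumeration oracle implements
independently. The OR is the sample cross-product ad/bc; a Haldane 0.5
correction is applied only when a cell is zero and is flagged in the
result. A covariate-adjusted logistic fit (Wald test, perfect separation
detected and reported with its direction) is emitted alongside.

**Hardy–Weinberg.** 1-df goodness-of-fit chi-square of the genotype counts
against proportions computed from the observed allele frequency;
monomorphic sites return statistic 0, P = 1 by convention.

## Multiplicity: two FDR variants and the Simes combination

Within each stratum × contrast cell the nine SNP P-values are FDR-adjusted.
`fdr_mode="bh"` is the textbook Benjamini–Hochberg step-up (delegated to
statsmodels). `fdr_mode="paper"` — the default — is plain rank scaling

    adj_i = min(1, p_i · N / r_i),   r_i = #{j : p_j ≤ p_i},

i.e. maximum rank under ties and no monotonicity pass. The two differ
exactly when the rank-scaled sequence is non-monotone; the published
reference tables for this panel contain such pairs (e.g. an adjusted
(0.158, 0.111) from raw (0.079, 0.111), and tied pathway values 2.15E-03
where BH's running minimum would differ), so only the `paper` variant
regenerates them. The variant is deliberately kept, clearly named, and
documented as *not* the statistically standard choice; `bh` output is
never larger than `paper` output (property-tested).

Pathway-level combination uses the Simes rule over the member SNPs'
FDR-adjusted values, p = min_m N·P(m)/m on the ordered list, capped at 1 —
valid under independence or positive dependence, super-uniform under the
null (checked empirically at N = 8). Substituting P_FDR for raw P at this
stage is the pipeline's defining convention; a raw-P option exists behind
a flag. The combined pathway values are then FDR-adjusted (same mode)
across the gene sets within the cell; sets with no genotyped member are
flagged and excluded from that denominator.

## Genetic urate risk scores

Weighted GRS = Σ_j N_j β_j over a pathway's member loci (eight each; the
two lists differ only in *PKD2*'s rs2728121 vs *SLC16A9*'s rs2242206);
unweighted GRS = Σ_j N_j. Default weights are the male per-allele urate
betas of the same panel — in-sample weighting, as the reference analysis
used; external weight tables are accepted. Samples missing any member
locus are excluded and reported. "Variance explained" is the univariate R²
(squared Pearson correlation of score and urate) within the stratum; the
incremental R² over an age-only model is emitted as a secondary column
because the reference definition is ambiguous. Binary outcomes are tested
by age-adjusted logistic regression; urate by age-adjusted OLS. Risk-bin
summaries use equal-frequency deciles by default (the binning of the
reference figure is unspecified); bins are merged with a warning when
distinct score values run out.

## Expression comparison

Inputs are already-normalised relative expression values (genes × samples)
with control / hyperuricemia / gout labels; ΔΔCt-style preprocessing is
out of scope. Outliers are removed once per gene × group by the Tukey
1.5·IQR box-plot rule before testing as well as plotting — the reference
description is ambiguous on whether removal precedes testing, so this is
config-reversible (`remove_for_test=False`). Group pairs are compared with
the two-sided Wilcoxon rank-sum test: exact distribution for combined
n ≤ 20 without ties, normal approximation with tie correction otherwise.
Pathway-level P is the Simes combination over member genes' raw P-values
(no FDR substitution at this stage).

## Synthetic cohort generator

The generator produces the structure the pipeline assumes, no more:

- genotypes drawn independently per SNP as Binomial(2, MAF) — exact
  Hardy–Weinberg proportions, no LD, no population structure, no
  genotyping error. Nothing downstream consumes LD, which is why it is
  not modelled;
- urate = `urate_mean` + Σ β_j N_j · (male indicator, unless
  `male_only_effects` is off) + 0.5·(age − mean age) + 60·I(male) +
  N(0, `urate_sd`), floored at 1 µmol/L. Default β are the panel's male
  per-allele effects (−11.09 to +10.11 µmol/L); the male-only default
  mirrors the male-restricted genetic effects the panel was characterised
  with. Covariate effects default to nonzero so that the adjustment code
  path is actually exercised;
- defaults `urate_mean = 350`, `urate_sd = 80` µmol/L, sex ratio 0.5: no
  cohort-level urate mean/SD is published for the reference population, so
  these were set once to realistic serum-urate values that place roughly a
  third of samples above 417 µmol/L (the reference cohort's 1,387/4,332
  split) and are config-exposed;
- gout by a urate-mediated liability: logit = logit(`gout_base_rate`) +
  `gout_urate_slope`·(urate − mean), defaults 0.05 and 0.01/µmol/L. Direct
  per-SNP gout effects are available but default to zero, encoding the
  hypothesis that SNP→gout association flows through urate. Gout overrides
  hyperuricemia in the status label;
- expression: log-normal, exp(N(shift, σ)) per gene × group, default group
  sizes 58/85/70 (control/HUA/gout) matching the reference expression
  design, default shifts zero.

Fixing the seed fixes every output bit-for-bit. Because the generator
omits LD, assortative structure, measurement error and treatment effects
on urate, passing tests demonstrate the *statistical machinery* is
correct and calibrated — not that real cohorts would reproduce any
particular effect size.

## Numerical choices and degenerate inputs

- P-values are validated into [0, 1] everywhere; adjusted values cap at 1.
- Fisher degenerate case (all alleles identical in both groups): OR
  undefined, P = 1, flagged. Logistic |log-OR| > 15 is treated as
  separation.
- The association scan never aborts: per-cell failures become flagged rows
  and flagged rows are excluded from the cell's FDR denominator.
- Result tables are written with 17 significant digits so a write→read
  round trip is identity to 1e-12 relative.
- Quartiles (Tukey fences, box-plot summaries) use linear interpolation
  (NumPy default).
- Effect correlation uses odds ratios on their natural scale by default:
  from the rounded published inputs this reproduces the reference R² of
  0.772 more closely (≈ 0.767) than the log-OR alternative (≈ 0.79);
  `log_or=True` provides the alternative.

## Problem sizes used in the test suite

Deterministic reproduction checks run on the published nine-SNP columns
directly. Calibration checks use 1,000 null replicates at n = 2,000
(deviance, Fisher, Simes type-I error bands [0.035, 0.065] at α = 0.05);
parameter recovery uses one n = 20,000 cohort (each generative β within
its 95% CI for ≥ 8/9 SNPs); GRS decile monotonicity uses n = 20,000 for
the acceptance check and 25 × n = 4,000 seeds for the replicate version.
These sizes were chosen to keep Monte-Carlo error well inside the asserted
bands while the full suite stays fast.

## Known limitations

- The `paper` FDR variant is a reconstruction from printed values; the
  original analysis code is not public, and the variant is internally
  identifiable only through its non-monotone and tied outputs.
- Published pathway values recombine from printed per-SNP inputs to ~1%
  only where those inputs carry ≥ 3 significant figures; cells whose
  inputs are printed to 1–2 figures (e.g. 0.009) recombine to ~3.5%.
- Cohort-level per-SNP effect sizes, GRS variance fractions and logistic
  coefficients of the reference study cannot be reproduced without the
  (undeposited) cohort; the suite substitutes calibration, oracle and
  recovery properties for them.
- One SNP per gene is assumed when resolving set membership; if several
  SNPs per gene are supplied they all enter the Simes list (SNP-level,
  not gene-level, combination).
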