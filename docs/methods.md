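# Methods

## The statistical procedure

The package tests whether rare alleles aggregate in a gene differently in
cases than controls, across several independently collected case-control
studies that share no individual-level harmonisation beyond a common
covariate convention.

**Collapsing.** Within a gene interval (1-based inclusive; BED input is
converted on read), the qualifying variants are those with study-level
minor allele frequency in `[maf_min, maf_max]` (defaults 0 and 0.03, both
ends inclusive) and imputation INFO ≥ 0.4.  Their dosages are averaged
per sample into the gene dosage `D = (Σ Gᵢ)/n`, which keeps `D` on the
same [0, 2] scale as a single variant's dosage.  A sample missing some of
the qualifying dosages is averaged over the ones it has (its effective
`n` shrinks); a sample missing all of them is excluded from that gene's
test.  Risk and protective alleles are pooled — no direction-aware
weighting — which trades power for type-I control, since orienting
alleles by their observed effect before testing would inflate the null.

**Per-study regression.** Case status is regressed on `D` (or a single
SNP's dosage) by maximum-likelihood logistic regression with Wald
inference, adjusting for age, sex, education and any `PC*` columns, with
the APOE-ε4 term appended in conditional runs.  Linear regression is
available as an option (`family="linear"`) for comparison with
linear-model burden engines, but logistic is the default because the
phenotype is binary and the per-study effect sizes are then log odds
ratios.  Degenerate fits — zero-variance predictor, separation,
non-convergence, non-finite standard errors — are flagged non-estimable
rather than raised, and propagate as `?` in direction strings.
Zero-variance covariate columns are dropped before fitting, so adjusting
for a constant (e.g. an ε4 column in a study with no carriers) equals not
adjusting, exactly.

**Meta-analysis.** Per-study Z scores are combined Stouffer-style with
weights `w = √N_E`, `N_E = 4/(1/N_cases + 1/N_controls)` — the
sample-size scheme of the standard GWAS meta-analysis tools.  `N_E`
equals twice the per-arm count for a balanced study and is dominated by
the smaller arm otherwise, which is why the 259-case Framingham-shaped
study contributes little despite its 4,323 controls.  Weights are scale
free: multiplying every `N_E` by a constant leaves `Z_meta` unchanged.
Significance is Bonferroni over the gene count (0.05/28,517 ≈ 1.8×10⁻⁶
for a genome-wide hg19 scan; 0.05/G for a G-gene simulation).

**Education.** Years of schooling are mapped to categories 1 (≤ 4),
2 (4–10], 3 (10–15], 4 (> 15) and the category is treated as a continuous
covariate, with missing values imputed to the study mean.  The published
convention this follows prints the third category as "11–15"; the
implementation uses 10 < years ≤ 15 so the partition has no gap, which
agrees with the convention's own boundary examples (10 → 2, 12 → 3).

**Two-stage design.** Stage 1 scans every gene.  Stage 2, run only on
stage-1-significant genes, tests each SNP in the gene individually,
meta-analyses, and keeps SNPs with meta P < 0.05, meta Z > 0 (risk
direction only) and MAF in [0.5%, 3%] — the floor excludes ultra-rare
variants whose imputation quality is poorest.  The MAF window is applied
per study: a SNP outside the window in one study is `?` there but may
still contribute elsewhere.  The confirmatory gene test then collapses
only the selected SNPs.  Because stage 2 reuses the stage-1 data, its P
values are confirmatory in-sample, not independent replication; the run
log says so explicitly.

**Conditional analysis.** Two diagnostics of ε4 dependence: (i) the scan
is re-run with the ε4 count (genotyped, preferred) or imputed ε4 dosage
appended as a covariate, and paired with the unadjusted results; (ii) the
variance inflation factor `VIF = 1/(1−R²)` from regressing `D` on ε4
*plus the other covariates of the actual design* — not `D` on ε4 alone —
since what matters is collinearity within the fitted model.  An
ε4-independent signal keeps its Z and shows VIF ≈ 1; a signal carried by
LD with ε4 collapses toward zero once ε4 is in the model.

## Quality control

Genotyped variants: drop if MAF < 1%, call rate < 95%, or exact HWE
P < 10⁻⁶.  Imputed variants: drop if INFO < 0.4 (INFO exactly 0.4 is
kept; thresholds are strict inequalities on the "bad" side throughout).
The HWE test is the exact conditional test: given the observed allele
counts, the probability of each compatible heterozygote count is computed
by a two-sided recurrence from the distribution mode (numerically stable
for large samples), and the P value sums the probabilities no larger than
the observed one (tolerance 1+10⁻¹² for ties).  It is applied to hard
calls only — dosages within 0.1 of an integer — because the conditional
distribution assumes integer genotypes.

Samples: drop on call rate < 95%; then heterozygosity outliers — per-sample
heterozygosity rate converted to a z score against the cohort mean/SD,
two-sided normal P, Benjamini–Hochberg at FDR 1% (the published pipelines
name only "FDR < 1%"; this normal-approximation version is a declared
approximation of the GenABEL-style check); then pairwise mean IBS,
`(2 − |g₁−g₂|)/2` averaged over shared non-missing hard calls, removing
the lower-call-rate member of any pair above 0.95 (ties broken by sample
order, greedily in sample order, for determinism).  With fewer than three
samples the distributional steps are skipped with a warning.  QC is
idempotent on clean data; the heterozygosity step, being relative to the
current cohort, is only statistically (not structurally) idempotent.

## The synthetic cohort generator

What it emulates: the six-study shape of the published AD meta-analysis
(post-QC quotas 350/169, 53/125, 779/803, 632/1843, 2098/2095, 259/4323;
4,171 cases and 9,358 controls in total, in the fixed direction-string
order), rare imputed dosages, covariate-driven disease risk, a strong
ε4-like confounder, and case-control ascertainment.

* **Gene map.** Genes are contiguous 50 kb intervals on one synthetic
  chromosome, each with a uniform random count of variants (default
  4–10) at random positions.  Population MAFs are drawn from
  Beta(0.6, 30) truncated to [0.001, 0.05] — mass concentrated below 3%
  with a realistic ultra-rare tail; the spectrum of real imputed panels
  is not published per study, so this is a modelling default, exposed in
  the config.
* **Genotypes.** Binomial(2, MAF) per variant — Hardy–Weinberg, no LD
  between variants except the optional confounder block.  Variants
  monomorphic in a generated study are redrawn up to 100 times, then
  kept for QC to handle (keeps variant counts as configured).
* **Confounder.** ε4-like counts are Binomial(2, 0.15) per person, with
  a per-allele log OR of log 3 by default — the effect size and carrier
  frequency of APOE ε4 in European-ancestry cohorts.  With
  `confounder_ld_gene` set, that gene's rare alleles are drawn
  Binomial(ε4 count, MAF/0.15): they exist only on ε4 haplotypes
  (D′ = 1), producing a marginal signal that is entirely confounding.
* **Disease model.** Logistic: intercept (default −1, baseline
  prevalence ≈ 27% at covariate means) + per-causal-gene log OR × true
  gene dosage + ε4 effect + age (0.03/yr, centred at 75), sex (0.2),
  education (−0.15/category, centred), PCs (0 by default).  Case status
  is Bernoulli; individuals are drawn in batches and kept until the
  exact case/control quotas are filled (rejection sampling), which
  reproduces fixed post-QC counts and — because ascertainment on a
  logistic outcome preserves slopes — leaves the causal log ORs
  estimable without correction.
* **Imputation noise.** Each hard genotype's posterior is a
  (1−e)/e mixture of a point mass and the variant's empirical genotype
  distribution; the emitted dosage is the posterior mean
  `(1−e)g + e·μ` and INFO is `1 − mean(posterior var)/(2θ(1−θ))`,
  clamped to [0, 1], with INFO ≡ 0 for monomorphic columns.  Per-variant
  rates are Uniform(0, 2ē) (capped below 0.5) so a nonzero mean error
  spreads INFO across variants and exercises the INFO < 0.4 filter.
  With e = 0 the dosage equals the genotype and INFO = 1.
* **Covariates.** Age ~ N(75, 6.5²) rounded to 0.1; sex Bernoulli(0.45);
  education multinomial (0.05, 0.25, 0.40, 0.30) over categories 1–4
  with a 5% missing rate (to exercise mean imputation); PCs standard
  normal.

What it does **not** emulate — hence what passing tests do not show about
real data: linkage disequilibrium within genes and with flanking regions;
population stratification and relatedness structure (PCs are noise here,
not ancestry; the Framingham pedigree problem is out of scope); batch or
platform effects between studies; reference-panel imputation error, which
is correlated across variants and samples rather than independent;
allele-frequency differences between studies; and any realistic gene
length/variant density distribution.

## Numerical choices

* Dosage files round to 3 decimals (VCF `DS`) or 5-decimal genotype
  probabilities (.gen); round-trip tests assert 5×10⁻⁴ agreement.
* Missing dosages are `NaN` internally, `.` in VCF, an all-zero triple in
  .gen — never 0.
* The weighted-Z combination and the HWE recurrence are both checked
  against independent oracles (brute-force Stouffer; closed-form gammaln
  enumeration) to 10⁻¹²/10⁻¹⁰ relative.
* Logistic fits use Newton iterations (statsmodels), max 200, with
  non-convergence flagged rather than trusted.
* Test and acceptance problem sizes — 4 studies × 2,000 samples × 100
  genes for null calibration, n = 8,000 single-study replicates for
  recovery, ~13,000 samples × 200 genes for the scan-power check — were
  chosen as the smallest sizes at which the statistical properties under
  test (uniform null P, 2-SE coverage, 80% power at OR 1.7) are stable;
  the power check uses single-variant genes because collapsing power
  scales with sd(D) ≈ √(2·MAF/n_variants), and a per-unit-D effect of
  log 1.7 at that sample size is only detectable with sparse genes.

## Known limitations

* The burden engine is logistic, not the linear-regression engine of the
  original gene-based tools; Wald Z signs and the meta machinery are
  unaffected, but per-study betas are on the logit scale.
* Per-sample missing-dosage handling (average over observed variants) is
  a declared substitute — the published engines do not document theirs.
* The heterozygosity-FDR screen is a normal approximation; heavy-tailed
  heterozygosity distributions would make it conservative.
* Stage-2 confirmation is in-sample; treat its P values as descriptive.
* IBS is O(n² m); use `ibs_variant_subset` for large cohorts.
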