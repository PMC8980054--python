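# Methods

`twinewas` implements the statistical chain of an epigenome-wide
association study (EWAS) of a binary trait — the motivating application is
left-handedness — in cohorts that mix twin families and unrelated
individuals, together with a synthetic cohort generator that provides
ground truth for every stage. This note records the models, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
data can and cannot establish.

## Per-CpG association

Methylation beta-values (the methylated fraction at a CpG, in [0, 1]) are
the outcome; the binary trait (1 = left-handed) plus covariates form the
design. Two estimators:

- **OLS** (`estimator="ols"`): classical standard errors, t reference with
  residual degrees of freedom. For unrelated cohorts.
- **Cluster-exchangeable estimating equations**
  (`estimator="cluster-exchangeable"`): Gaussian mean structure, an
  exchangeable working correlation within `family_id` clusters, robust
  sandwich standard errors, normal reference. For twin cohorts. The
  working correlation is iterated with the usual moment estimator until
  the maximum parameter change is below 1e-8 (cap 100 iterations);
  non-convergent CpGs fall back to an independence working correlation
  with sandwich errors and are counted in a warning. The sandwich
  covariance carries a G/(G−p) cluster degrees-of-freedom correction
  (G clusters, p parameters) by default: the raw Liang–Zeger sandwich
  underestimates the variance by roughly that factor, which at
  epigenome scale shows up as a ~3% inflation of null z-scores and a
  clear failure of p-value uniformity. `gee_df_correction=False`
  reproduces the raw sandwich exactly (and matches `statsmodels.GEE`).

The estimating-equation fit is a closed-form batched implementation
(exchangeable cluster covariances invert analytically), vectorised across
all CpGs that share a missingness pattern. This is what makes
epigenome-scale calibration runs and the genome-wide null experiments
feasible on one CPU; the unit tests pin it against `statsmodels.GEE`
coefficient-for-coefficient (agreement ~1e-13).

Missing data are handled per CpG by complete cases, so per-analysis sample
sizes may differ across CpGs. CpGs with fewer complete cases than
`min(10, n)` (or not enough residual degrees of freedom) get missing
statistics and a warning. Categorical technical covariates (plate, array
row) expand to indicator columns with the first level as reference.

## Meta-analysis, multiplicity, inflation

Cohorts are combined per CpG by inverse-variance fixed-effects
meta-analysis (weights 1/SE²), on the intersection of CpGs present with
finite statistics in every cohort. Multiplicity: Bonferroni (0.05 divided
by the number of CpGs tested), Benjamini–Hochberg q-values (default), and
a fixed-λ (λ = 0.5) Storey variant, π̂₀ = min(1, #{p > 0.5} / (0.5 m)).
Inflation is summarised by the genomic-control factor
λ_GC = median(z²)/median(χ²₁) plus a median/MAD empirical null
(mean = median(z), sd = 1.4826·MAD). These replace the Bayesian
mixture-model inflation estimator sometimes used for EWAS: they are
deterministic, dependency-free and sufficient to certify "no inflation";
they do not decompose inflation into confounding vs. bias components the
way the Bayesian estimator does.

An important subtlety the null experiments expose: covariates with
genome-wide effects (smoking, cell composition) that are *omitted* from
the model leave a residual component shared across all CpGs. Within one
dataset this common factor shifts every test statistic by the same random
amount, deflating the apparent dispersion of z (λ < 1, non-uniform p).
The fully adjusted model restores calibration; this is the model the
calibration suite and the acceptance script use.

## Differentially methylated regions

Candidates are found on the meta-analysis summary: per chromosome, CpGs
with p < 0.05 and a common effect sign are merged into maximal runs where
consecutive qualifying CpGs are ≤ 500 bp apart (a total-span variant is
available by flag). Runs of ≥ 2 CpGs are candidates; every contiguous
sub-window of ≥ 2 CpGs inside a run is evaluated. The sign constraint
reflects the reading of a DMR as coherently hyper- or hypomethylated and
can be switched off.

The Bonferroni denominator is the **genome-wide count of potential
regions**: all contiguous ≥2-CpG sub-windows of maximal ≤500 bp-gap runs
over *all* CpGs, before any association filter (recorded in the output
metadata alongside the number of windows actually evaluated). Counting
only the windows whose members happened to reach nominal significance
would shrink the denominator exactly when selection has already inflated
the surviving region statistics; with strongly correlated CpG blocks this
candidate-only convention produces family-wise error rates near 1 on null
panels, while the potential-region denominator — which is data-independent
given the manifest — restores control. The per-region GLS z itself is
exactly standard normal under the null (pinned against a dense-matrix
oracle); the correction concerns the search over regions only.

The region statistic in each cohort is the generalized-least-squares
combination of the member-CpG effects b with covariance V = S·R·S, where
S = diag(member SEs) and R is the Pearson correlation of the member CpGs'
residualized methylation in that cohort:

    effect = (1' V⁻¹ b) / (1' V⁻¹ 1),   se = (1' V⁻¹ 1)^(-1/2).

R is regularized as R ← (1−ε)·R + ε·I with ε = 0.01 after capping
off-diagonals at ±0.99, which keeps V invertible under duplicated or
near-duplicated probes; V is factorised by Cholesky. With R = I the
statistic reduces exactly to the inverse-variance meta-analysis of the
member CpGs; with perfectly redundant members the SE tends to the
single-CpG SE. Per-cohort region statistics are combined across cohorts by
inverse-variance meta-analysis, p-values are multiplied by the number of
regions tested (capped at 1), and each region carries the mean absolute
member-CpG effect (Σ|bᵢ|/n) as its descriptive effect size. The
representative of each maximal run is its sub-window with the largest
meta-analysis |z|.

## GWAS-proximity enrichment

For a locus set (SNPs below a GWAS p cutoff; 1e-8, 1e-6, 1e-5 are the
configured defaults), each CpG is flagged if it lies within the window of
any same-chromosome SNP. "1 Mb window" is implemented as distance
≤ 500 kb (a 1 Mb window centred on the SNP); the flag is configurable to
±1 Mb. The test regresses |z| on the flag — with a binary regressor the
OLS slope equals the difference of group means of |z| — and the standard
error is the SD of the slope over 2000 bootstrap resamples of CpG rows,
with a two-sided normal p-value and a percentile CI as secondary output.
A control mode swaps in loci of an unrelated trait, and an exclusion list
(e.g. CpGs driven by mQTLs) is honoured before anything else; exclusion
commutes with annotation by construction. Simple row resampling ignores
the spatial correlation of |z| along the genome; with correlated blocks
the bootstrap SE is mildly optimistic, a known limitation of this design.

## Discordant-MZ within-pair analysis

Complete MZ pairs with discordant handedness are paired deterministically
(ordered by family id; MZ families with more than two assayed members are
excluded with a warning). Methylation is residualized on pair-varying
covariates — technical covariates, cell proportions, BMI/smoking in
adults — fitted on *all* twins for stability; pair-constant covariates
(age, sex, gestational factors) are rejected because differencing removes
them exactly. Per CpG the paired t-test on left-minus-right residual
differences gives effect = mean(d), se = sd(d)/√n, df = n−1. Pairs missing
a CpG are dropped for that CpG only. The design cancels everything shared
within a pair, which the tests verify by planting strong family-level
confounding and checking the within-pair estimate stays centred at zero.

## Scores and liability-scale R²

A score is Σₙ wₙ·xₙᵢ over features (CpG beta-values or SNP dosages), with
weights from a discovery analysis of a *disjoint* cohort, then
standardized to mean 0 / SD 1 (so rescaling all weights is a no-op).
Missing feature values are mean-imputed per feature; the coverage fraction
of the weight table is reported. CpG inclusion thresholds 1e-1, 1e-3,
1e-5 give nested weight tables.

Variance explained uses linear-probability-model increments:
R²(covariates + score) − R²(covariates), and for methylation scores also
the increment over covariates + PGS. Observed-scale values map to the
liability scale by the ascertainment-corrected transformation

    t = Φ⁻¹(1−K),  z = φ(t),  m = z/K,
    C = [K(1−K)]² / [z² P(1−P)],
    θ = m(P−K)/(1−K) · (m(P−K)/(1−K) − t),
    R²_liab = C·R²_obs / (1 + C·θ·R²_obs),

with K the population prevalence (an explicit required parameter) and P
the sample case proportion; θ = 0 when P = K. The transform is validated
end-to-end by simulation: cohorts generated with a true polygenic
liability R² of 0.05 at K = 0.10 are estimated at 0.05 within Monte-Carlo
error, which guards the (hand-entered) constants of the formula. Small
negative observed increments (possible for incremental R²) pass through
the same formula.

## Synthetic cohorts

The generator emulates the study designs the pipeline targets: an adult
blood twin-register cohort (default n = 2682; ≈40% of samples in MZ pairs,
30% in DZ pairs, the rest singletons; left-handedness prevalence 12%), an
unrelated adult cohort, and a child buccal variant with gestational-age,
birth-weight and maternal-smoking covariates.

- **Phenotype.** Liability-threshold model: liability = √r²·PGS_std +
  √c²·family + √(1−r²−c²)·unique, case iff liability > Φ⁻¹(1−K). The
  family component is shared fully by MZ and half by DZ co-twins;
  c² defaults to 0.25, the ballpark of twin-study heritability estimates
  for handedness. The polygenic component comes from simulated dosages
  (Mendelian transmission within families, so MZ co-twins have identical
  genotypes) with r² = `pgs_liability_r2` (default 0: the null).
- **Methylation.** Logit-scale linear model per CpG: intercept
  (N(0, 1.2²) clipped to ±3.5, giving baselines across (0.03, 0.97)) +
  covariate effects + per-CpG family component (variance share 0.15,
  MZ share fully, DZ half) + block component shared by CpGs of the same
  block (variance share = `block_rho`, so within-block residual
  correlation equals `block_rho` by construction) + unique noise; the sum
  is scaled to `sigma_logit`, passed through the logistic function and
  clipped to [1e-6, 1−1e-6]. `sigma_logit` defaults to 0.2: with
  logistic-density slopes this gives residual beta-scale SDs around
  0.02–0.05, the magnitude implied by per-CpG standard errors in blood
  EWAS of a few thousand samples. CpGs are laid out in blocks of 2–6
  probes 150 bp apart, with 20–200 kb gaps between blocks across 22
  chromosomes; cohorts of one study share the layout via
  `manifest_seed`.
- **Planted effects.** Case−control effects are specified on the
  beta-value scale and converted to the logit scale by dividing by the
  mean logistic density over the realised linear predictor, an
  expected-derivative refinement of the delta method. The naive delta
  method at the intercept under-recovers by roughly σ²/16 relative at
  mid-scale CpGs, which would consume most of a 10% bias budget; the
  expected-derivative version is unbiased to first order, and recovery
  tests confirm relative bias within Monte-Carlo error of zero. Infeasible
  plants (target mean beta outside (0, 1), or >1% of case samples clipped)
  raise an error naming the CpG.
- **Covariates.** Age (shared within family), sex (shared in MZ pairs),
  BMI (family + unique), smoking (Bernoulli 0.25), blood cell proportions
  (Dirichlet around neutrophils 52%, lymphocytes 33%, monocytes 8%,
  eosinophils 5.5%, basophils 1.5%), plate (8 levels) and row (12 levels)
  with small per-CpG random plate effects so residualization is exercised.
- All randomness flows from the single `seed` through one
  `numpy.random.Generator`; identical configs are byte-identical.

What the generator does **not** model: array probe-level artefacts and
normalization residue, bimodal Type-I/Type-II intercept structure,
X-inactivation, long-range correlation beyond the block, cell-composition
confounding with the trait, and LD structure among SNPs (dosages are
independent across loci apart from family transmission). Passing tests
therefore certify the statistical machinery — calibration, recovery,
algebra — not robustness to array artefacts.

## Problem sizes in the test and acceptance suites

The calibration and recovery experiments run at desk scale, chosen so the
Monte-Carlo error of each check is several times smaller than its
tolerance: the global-null cohort uses 20,000 CpGs × 1,000 twin-structured
samples; enrichment type-I calibration uses 200 summary-level seeds of
20,000 CpGs with 2,000 bootstraps each; DMP recovery uses 50 seeds × 5
planted CpGs at n = 2,000; DMR power uses 50 seeds × two cohorts of
n = 2,000 over a 500-CpG panel of 5-CpG blocks; PGS recovery uses 50
seeds at n = 2,000. The full pipeline behaves identically at 450k-array
scale, only slower and more memory-hungry (the beta matrix is dense
float64).

## Known limitations

- The exchangeable working correlation assumes one correlation per family
  regardless of zygosity; with MZ and DZ pairs mixed it estimates a
  compromise value. Sandwich errors keep inference valid regardless.
- The bootstrap enrichment SE ignores spatial correlation of |z|.
- The liability transform assumes the standard threshold model; it is not
  exact for scores entering through non-probit links.
- Storey's π₀ uses a single λ = 0.5 rather than a smoother.
- The PGS pathway consumes an externally supplied (or simulation-truth)
  weight table; LD-aware reweighting of GWAS summary statistics is out of
  scope.
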