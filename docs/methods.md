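# Methods

## Setting and model

The package analyzes phenotypes whose genetic architecture depends on the
genotype of a single strong biallelic effect modifier. The modifier is
assumed directly genotyped (never imputed) and coded by ALT-allele count:
0 (GG wild-type homozygote), 1 (GA heterozygote), 2 (AA variant
homozygote). AA-only analysis is not offered — with a strongly protective
modifier the AA stratum has too few exposed individuals to support a
scan — and AA carriers are excluded from all interaction models, where
the modifier is coded GG = 0 / GA = 1.

Association models, per variant with dosage x ∈ [0, 2]:

- quantitative: `log2(intake + 1) = β0 + β_SNP·x + Σ βk·ck + ε`, fit by
  OLS unstratified or within a modifier stratum;
- binary: the same linear predictor on the logit scale, fit by ML (IRLS)
  or by Firth's bias-reduced likelihood;
- interaction: `β0 + β_mod·x_mod + β_SNP·x + β_int·x_mod·x + Σ βk·ck`,
  reporting (β_SNP, β_int) with their full covariance (model-based by
  default, sandwich on request).

Default covariates: age, age² (always derived from age inside the design
matrix), sex, and 10 principal components. Inference is Wald throughout,
and every p-value is computed and stored in log10 space so statistics as
extreme as |z| ≈ 200 keep finite, comparable p-values. scipy's
`chi2.logsf` underflows for such statistics, so the 1-df tail routes
through the stable normal `logsf` and the 2-df tail uses the exact form
log sf(x) = −x/2.

Effect-allele convention: the effect allele is always ALT and EAF is the
ALT frequency (the summary-statistics convention of the major
meta-analysis tools); flipping alleles negates β, maps EAF → 1 − EAF and
leaves p unchanged.

## Meta-analysis

Fixed effects use inverse-variance weights w = 1/se²; heterogeneity is
Cochran's Q with I² = max(0, (Q − df)/Q)·100 clipped to [0, 100]; random
effects use the DerSimonian–Laird tau². Study-level SEs can be corrected
by a supplied LD-score-regression intercept: when the intercept exceeds
1, every SE is multiplied by the intercept itself (a `sqrt_convention`
switch offers the alternative √intercept convention found elsewhere in
the literature; the plain-multiplication rule is the default). Estimating
the intercept is out of scope — it is an input. Variants present in only
a subset of studies are pooled over the contributing studies and then
subjected to the inclusion filter (k ≥ 3 studies and total n ≥ 20,000 for
unstratified or interaction analyses, ≥ 10,000 for stratified analyses;
boundaries inclusive).

The 2-df joint meta-analysis pools per-study bivariate estimates by
multivariate fixed effects, V_pooled = (Σ V_i⁻¹)⁻¹, and tests
b′V⁻¹b against χ²₂. QC applies, in order, the MAF ≥ 0.05 filter (any
contributing study), the per-coefficient heterogeneity filter
(HetP < 0.001 on either coefficient), and the cor ≥ 0.7 filter, logging
counts at each step so the funnel is auditable. The order is a package
choice — the filters are defined jointly in the source methodology
without a stated sequence — and cor is computed from the pooled
covariance (per-study values are also available; whether the original
filter was per-study or pooled is ambiguous, and pooled is the default
here). Genomic control for the joint test uses λ = median(χ²)/(2 ln 2)
and divides statistics by λ only when λ > 1 (standard genomic-control
practice; deflation is never "corrected up").

## LD, haplotypes, conditional analysis

D′ and r² follow the textbook definitions from two-locus haplotype
frequencies; unphased input is resolved by EM over diplotype expansions
with deterministic uniform initialization, convergence at max frequency
change < 1e-8 or 1,000 iterations, and a non-decreasing log-likelihood
asserted at every step. At most 20 loci are accepted (the expansion is
exponential in the number of heterozygous sites).

The diagnostic configuration of interest is a proxy variant with D′ = 1
and small r² to the modifier: one of the four two-locus haplotypes is
absent, and a proxy allele carried exclusively on the modifier's
wild-type haplotype shows a marginal association opposite in sign to its
within-stratum effect whenever the modifier effect is large and of the
same sign. The synthetic generator plants exactly this structure, and the
pipelines module reproduces the flip end-to-end.

Loci are defined greedily: the most significant genome-wide-significant
SNP seeds a locus and absorbs significant SNPs within 1 Mb (ties broken
by smaller position). Clumping iterates variants by ascending p, removing
variants within ±250 kb at r² > 0.1 (distances base-pair
center-to-center, window inclusive; index variants always retained).
Approximate conditional analysis maps marginal estimates to the
standardized-genotype scale, solves b_joint = R⁻¹·b_marginal with
covariance R⁻¹/n against a genotype reference panel, and maps back to the
allele-count scale. This is the single-reference simplification of the
published conditional estimator — per-SNP effective-sample-size
bookkeeping is deliberately omitted — and an oracle test checks it
against individual-level joint regression at desk scale. Candidates with
|r| > 0.9 to the conditioning set are skipped as collinear. sd(y) is
profiled from the median of n·se²·var(g) across input variants, a
weak-effect approximation adequate for GWAS-scale effects.

## Additive interaction (RERI)

Per-study case-control fits use the logistic product-term model above,
with dosage or hard-call genotype coding per study. Coefficient vectors
(β_SNP, β_mod, β_int) are pooled by multivariate random effects under
b_i ~ N(b, V_i + Ψ) with Ψ unstructured PSD, estimated by maximizing the
likelihood over a Cholesky parameterization (Nelder–Mead on the profile
likelihood; GLS at the optimum gives the pooled vector and covariance).
REML is available and is recommended at small study counts, where the ML
Ψ̂ is biased downward; with only two studies Ψ is weakly identified and
the fixed-effects fallback (Ψ = 0) is used on optimizer failure, with a
warning. RERI = e^{β₁+β₂+β₃} − e^{β₁} − e^{β₂} + 1, with the delta-method
gradient (e^s − e^{β₁}, e^s − e^{β₂}, e^s), 95% CIs at z = 1.959964, and
suggestive significance when the CI excludes 0 (Bonferroni threshold
0.05/m, default m = 8 tests). The stacked-bar decomposition identity
jointOR = (OR_SNP − 1) + (OR_mod − 1) + RERI + 1 holds exactly by
construction. Sensitivity tools: Firth regression (Jeffreys-prior
penalized scoring, finite under separation — a zero cell in the saturated
one-predictor model reproduces the add-½-per-cell odds ratio exactly) and
seeded 1:k control subsampling without replacement.

The additive-null calibration experiment generates risks
p = p0·(1 + (RR₁−1)·g + (RR₂−1)·m) with p0 = 0.01 at n = 40,000, so
excess relative risks are exactly additive; the fitted ORs approximate
the RRs only in the rare-disease limit, which is why the defaults use a
rare outcome. Observed coverage of zero by the delta CI is ≈ 94% over 500
replicates — the delta interval is slightly anticonservative for this
convex functional, and the check accepts [92%, 98%].

## Polygenic scores

The phenotype is residualized once on the full sample (age, age², sex,
10 PCs) before the seeded 2:1 target/validation split (⌈2n/3⌉ target).
C+T uses clumping at 250 kb / r² 0.1 / p ≤ 1, a threshold grid from 5e-8
to 0.5 in 5e-5 steps (endpoints inclusive; input p-values floored at
1e-300), and selects the threshold maximizing target-set R² of the
simple regression on the residual phenotype; thresholds mapping to the
same variant count share a score, so R² is evaluated once per distinct
prefix and the smallest qualifying threshold is reported — selection is
fully deterministic. Raw-score mean and SD on the target set are frozen
as the standardization constants. A/T–G/C ambiguous variants are kept
(matching is by variant ID, not strand); missing variants at scoring time
are mean-imputed as 2·EAF from the model metadata; a best-guess mode
rounds dosages to hard calls. The combined score is the OLS fit of
`y_res = w0 + w1·G + w2·(1−G)·PRS_GG + w3·G·PRS_GA` on target GG/GA
individuals, and all R² values are simple-regression R² in percent.

## Synthetic-data generator

The generator is the package's study system. Defaults:

- modifier region: haplotype frequencies {G-G 0.58, A-G 0.25, G-A 0.17}
  drawn i.i.d. per haplotype (Hardy–Weinberg), giving a modifier ALT
  frequency of 0.17, proxy ALT frequency 0.25, D′ = 1, r² ≈ 0.068, and a
  structurally absent proxy-A/modifier-A haplotype;
- cohorts: six, sized (496, 1324, 1004, 786, 459, 13499) — the study's
  six-cohort structure at one-tenth scale, chosen as the package's
  desk-scale default; per-cohort effects are β + N(0, τ²), with τ² = 0
  giving homogeneous effects; one global seed, per-cohort streams spawned
  deterministically;
- background SNPs: MAF ~ Uniform(0.05, 0.5), independent per site, except
  inside declared LD blocks where haplotype alleles follow a
  latent-Gaussian AR(1) with the configured correlation (the realized
  allele correlation is lower than the latent one — a documented
  simplification; no recombination maps or demography are modeled);
- phenotype: latent y* = linear predictor + N(0, σ²) on the
  log2(g/day + 1) scale with σ = 2 and intercept 3 (median intake of a
  drinker ≈ 7 g/day); stored raw intake is max(0, 2^{y*} − 1), so the
  analysis transform recovers max(0, y*) exactly and never-drinkers arise
  from the censoring floor. No generative model is prescribed by the
  source methodology (it analyzes observed cohorts); this censored
  log-normal is a stand-in chosen to make the transform a round trip, and
  left-censoring attenuates stratum effect estimates toward zero — tests
  that assert effect recovery either use mild censoring or fit the latent
  scale;
- binary outcomes: Bernoulli from the logistic linear predictor;
  drinking status reads the main effect fields on the logit scale,
  disease risk has its own coefficient set; control subsampling to a
  target case:control ratio records the sampling fraction so intercepts
  remain interpretable;
- the modifier effect default (−1.8 per ALT allele, ≈ 16% of phenotype
  variance) mirrors a dominant single-locus determinant.

What the generator does **not** emulate: realistic human LD maps,
imputation error (all variants carry quality 1.0 unless set), population
stratification, assortative mating, or self-report measurement error.
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to those real-data features.

## Problem sizes and numerical choices

Test and reproduction runs use desk-scale sizes chosen as the package's
own defaults: null-calibration scans of 2,000 variants (KS uniformity)
and 50,000 variants at n = 400 for λ (median-based λ has SE ≈ 2.3/√m, so
50,000 statistics put 3 SE within ±0.03); 200-replicate oracle
comparisons; 500-replicate RERI coverage; 100-replicate PRS ordering with
discovery n = 8,000, scoring cohort n = 4,500, 20 causal SNPs of ±0.25
whose effects reverse sign between strata (interaction −0.5·sign). The
interaction-rich architecture is the regime where the combined score must
beat both the modifier alone and the main-effects-only score; with no
interactions and a null modifier the unstratified score wins, and both
directions are asserted.

Other numerics: OLS scans use the Frisch–Waugh–Lovell projection
(covariates QR-factorized once, slopes vectorized across variants);
monomorphic-in-stratum variants are flagged, not errors; logistic IRLS
uses step-halving with separation flagged on |β| > 15 or non-convergence
with saturated probabilities, and the Firth path is suggested or
substituted; EM initialization is uniform over consistent haplotypes
(deterministic); clumping ties break by position; the mv-meta Wald
ellipse at k ≤ 6 studies undercovers mildly because Ψ̂ is plugged in —
REML reduces but does not remove this, and the calibration test checks
superiority over fixed effects plus near-unbiasedness of Ψ̂ rather than
an exact nominal rate.

## Known limitations

- No mixed models/kinship correction, no X-chromosome conventions, no
  BGEN/PLINK-binary readers (VCF + TSV only; multiallelic records are
  skipped with a warning).
- Imputation itself, LD-score regression estimation, heritability,
  cross-ancestry genetic correlation, and functional annotation are out
  of scope; intercepts and external summary statistics are inputs.
- The conditional estimator assumes one LD reference for all summary
  statistics and weak effects; strong-effect regions (like the modifier
  region itself) should be conditioned with care — the source methodology
  likewise excluded its strongest region from conditional analysis.
- `jma_qc`'s cor ≥ 0.7 filter is aggressive when main and interaction
  estimates are near-independent or negatively correlated (as model-based
  covariances often are); it is exposed with the documented threshold and
  can be disabled by passing `cor_threshold=-1`.
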