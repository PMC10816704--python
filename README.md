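# stratgwas

Genotype-stratified GWAS against a strong effect-modifier variant, with
SNP×modifier interaction meta-analysis, LD/haplotype diagnosis of
proxy-SNP sign flips, additive-interaction (RERI) case-control analysis,
and interaction-aware combined polygenic scoring.

## The problem

Some phenotypes are dominated by a single strong variant that *modifies*
the effects of other loci. The canonical example is alcohol consumption in
East Asian populations: the *ALDH2* Glu504Lys variant (rs671, G>A)
inactivates acetaldehyde clearance, so heterozygous (GA) carriers drink
far less than wild-type (GG) homozygotes, and other alcohol-metabolism
loci act differently within each genotype. A conventional GWAS fits one
marginal effect per SNP and can miss — or even reverse — these
genotype-dependent effects. This package implements the full analysis
toolkit for that setting:

- **Stratified and interaction scans** (`stratgwas.assoc`). Per-variant
  linear/logistic regressions, run unstratified, within the GG or GA
  stratum, or jointly with an interaction term:

  `y = β₀ + β_mod·x_mod + β_SNP·x_SNP + β_int·x_mod·x_SNP + Σₖ βₖcₖ + ε`

  with the modifier coded GG = 0 / GA = 1 (AA carriers excluded), dosages
  in [0, 2], and covariates age, age², sex and 10 principal components.
  The quantitative phenotype is log₂(g/day + 1). Firth penalized logistic
  regression is included for extreme case:control imbalance.
- **Meta-analysis** (`stratgwas.meta`). Fixed-effects inverse-variance
  pooling with Cochran's Q and I², DerSimonian–Laird random effects,
  per-study SE correction by a supplied LD-score-regression intercept,
  inclusion filters (≥3 studies; total n ≥ 20,000 unstratified/interaction
  or ≥ 10,000 stratified), and genomic inflation λ.
- **2-df joint meta-analysis** (`stratgwas.jma`). Per-study bivariate
  (β_SNP, β_int) estimates pooled with their covariance; a 2-df Wald test;
  the `cor = IntCov/(StdErr·IntStdErr)` QC statistic; the
  MAF ≥ 0.05 / HetP < 0.001 / cor < 0.7 filter funnel; 2-df genomic
  control against the χ²₂ median 2 ln 2.
- **LD and haplotypes** (`stratgwas.ldhap`). D, D′, r² from phased or
  EM-resolved haplotypes; EM haplotype-frequency estimation; explained
  haplotype fractions; 1-Mb locus definition; LD clumping; and
  COJO-style approximate conditional analysis from summary statistics.
- **Additive interaction epidemiology** (`stratgwas.interact_epi`).
  Per-study logistic fits with a product term, multivariate random-effects
  pooling (ML or REML over an unstructured between-study covariance), and
  the relative excess risk due to interaction
  `RERI = e^{β₁+β₂+β₃} − e^{β₁} − e^{β₂} + 1` with delta-method CIs.
- **Polygenic scores** (`stratgwas.prs`). Clumping + thresholding
  (250 kb / r² 0.1 / p-grid 5e-8…0.5 step 5e-5), standardized scores
  frozen on a 2:1 target/validation split, and the combined score
  `w₀ + w₁·G + w₂·(1−G)·PRS_GG + w₃·G·PRS_GA` that encodes gene-gene
  interaction in prediction.
- **Synthetic cohorts** (`stratgwas.synthdata`). A multi-cohort generator
  with the key diagnostic structure: a three-haplotype modifier region
  (only G-G, A-G, G-A proxy-modifier haplotypes, so D′ = 1 with r² ≈ 0.07),
  LD-blocked background SNPs, a left-censored log-normal intake phenotype,
  and case-control outcomes with planted additive interaction.

## Worked example: the proxy-SNP sign flip

When a proxy allele occurs exclusively on the modifier's wild-type
haplotype, its marginal association absorbs the (large) modifier effect
with the opposite sign of its true within-stratum effect:

```python
from stratgwas import pipelines

res = pipelines.sign_flip_experiment(seed=7, n=30_000)
for k, v in res.items():
    print(f"{k}: {v:.4f}")
```

prints

```
beta_unstratified: 0.1979
beta_ga: -0.1282
absent_haplotype_freq: 0.0000
explained_fraction: 1.0000
proxy_modifier_r2: 0.0673
proxy_modifier_dprime: 1.0000
```

The proxy's true effect within GA heterozygotes is −0.2 on the
log₂(g/day+1) scale; the GA-stratified scan recovers a negative estimate
(attenuated by left-censoring of intake at zero), while the unstratified
scan reports +0.20 — a sign flip produced purely by the three-haplotype
LD configuration (D′ = 1, r² ≈ 0.07; the proxy-A/modifier-A haplotype is
absent, and EM haplotype estimation from the unphased genotypes confirms
the three observed haplotypes explain 100% of the sample).

A thin CLI mirrors the pipeline stages
(`stratgwas simulate|scan|meta|jma|cojo|loci|reri|prs|report`); see
`stratgwas --help`.

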