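"""Multi-cohort synthetic data with the statistical structure the
stratified-GWAS pipeline assumes.

The generator plants a strong biallelic effect-modifier locus (an
"rs671-like" variant, ALT frequency 0.17 by default) inside a
three-haplotype region shared with a proxy variant: the only proxy-modifier
haplotypes are G-G, A-G and G-A, so D' = 1 while r-squared is small. This
is the configuration that produces proxy-SNP sign flips between
unstratified and stratified scans. Background SNPs are drawn independently
per site, optionally organized into LD blocks with a latent-Gaussian AR(1)
haplotype correlation.

The quantitative phenotype is a left-censored log-normal on the
log2(grams/day + 1) scale: a latent Gaussian linear predictor y* is drawn,
and the stored raw intake is max(0, 2**y* - 1), so the downstream log2
transform recovers max(0, y*) exactly. Never-drinkers arise from the
censoring floor.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .data import GenotypePanel, PhenotypeTable

MODIFIER_ID = "mod_rs671like"
PROXY_ID = "proxy_rs79463616like"
MODIFIER_POS = 111_803_962
PROXY_POS = 111_784_000
MODIFIER_CHROM = "12"

#: the three observed proxy-modifier haplotypes and their frequencies;
#: the fourth (A-A) haplotype is absent.
DEFAULT_HAP_FREQS = {"G-G": 0.58, "A-G": 0.25, "G-A": 0.17}

#: the six cohort sizes at one-tenth scale (desk-scale default)
DEFAULT_COHORT_SIZES = (496, 1324, 1004, 786, 459, 13499)


@dataclass
class EffectSpec:
    """Effect sizes of the generative phenotype model.

    For the quantitative phenotype the linear predictor lives on the
    log2(g/day + 1) scale; for drinking status the same fields are read on
    the logit scale; disease risk has its own coefficient set
    (``disease_alpha``) on the logit scale.
    """

    beta0: float = 3.0
    beta_mod: float = -1.8            # per modifier ALT allele
    beta_snp: dict = field(default_factory=dict)     # variant id -> main effect
    beta_int: dict = field(default_factory=dict)     # variant id -> interaction with modifier
    gamma_cov: dict = field(default_factory=lambda: {"sex": 1.0})
    sigma: float = 2.0
    disease_alpha: dict = field(default_factory=dict)
    # disease_alpha keys: intercept, beta_mod, beta_snp {id: b}, beta_int {id: b}, gamma_cov {}

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class SimConfig:
    seed: int = 0
    cohort_sizes: tuple = DEFAULT_COHORT_SIZES
    hap_freqs: dict = field(default_factory=lambda: dict(DEFAULT_HAP_FREQS))
    n_background_snps: int = 200
    maf_range: tuple = (0.05, 0.5)
    ld_block_spec: tuple = ()          # sequence of (block_length, latent AR(1) rho)
    effects: EffectSpec = field(default_factory=EffectSpec)
    tau2: float = 0.0                  # between-cohort effect-size variance
    case_control_ratio: float | None = None

    def __post_init__(self):
        total = sum(self.hap_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"hap_freqs must sum to 1 (got {total})")
        if any(f < 0 for f in self.hap_freqs.values()):
            raise ValueError("hap_freqs must be non-negative")
        if any(n < 2 for n in self.cohort_sizes):
            raise ValueError("all cohort sizes must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if sum(bl for bl, _ in self.ld_block_spec) > self.n_background_snps:
            raise ValueError("ld_block_spec longer than n_background_snps")

    @property
    def n_cohorts(self) -> int:
        return len(self.cohort_sizes)


def _draw_background_mafs(config: SimConfig, rng) -> np.ndarray:
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=config.n_background_snps)


def _haplotype_alleles(hap_freqs):
    """Parse 'proxy-modifier' haplotype strings into (proxy_alt, mod_alt) 0/1."""
    haps, freqs = [], []
    for h, f in hap_freqs.items():
        a1, a2 = h.split("-")
        haps.append((int(a1 == "A"), int(a2 == "A")))
        freqs.append(f)
    return np.array(haps, dtype=np.int8), np.array(freqs, dtype=float)


def simulate_panel(config: SimConfig, n: int | None = None, rng=None,
                   background_mafs: np.ndarray | None = None) -> GenotypePanel:
    """Draw one cohort's genotype panel.

    Each individual receives two modifier-region haplotypes i.i.d. from
    ``hap_freqs`` (Hardy-Weinberg); background SNP haplotype alleles are
    Bernoulli(MAF) per site, with latent-Gaussian AR(1) correlation inside
    declared LD blocks. Fully reproducible from the seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n is None:
        n = int(sum(config.cohort_sizes))
    haps, freqs = _haplotype_alleles(config.hap_freqs)
    hap_idx = rng.choice(len(haps), size=(n, 2), p=freqs)
    region = haps[hap_idx]  # (n, 2, 2): [..., 0] proxy allele, [..., 1] modifier allele

    m = config.n_background_snps
    if background_mafs is None:
        background_mafs = _draw_background_mafs(config, rng)
    if len(background_mafs) != m:
        raise ValueError("background_mafs length mismatch")

    # latent-Gaussian haplotype alleles; AR(1) within blocks, independent elsewhere
    z = rng.standard_normal(size=(n, 2, m))
    start = 0
    for block_len, rho in config.ld_block_spec:
        for j in range(start + 1, start + block_len):
            z[:, :, j] = rho * z[:, :, j - 1] + np.sqrt(1 - rho**2) * z[:, :, j]
        start += block_len
    bg = (z < ndtri(background_mafs)[None, None, :]).astype(np.int8)

    phased = np.concatenate([region[:, :, [0]], region[:, :, [1]], bg], axis=2)
    dosages = phased.sum(axis=1).astype(float)
    modifier = phased[:, :, 1].sum(axis=1).astype(int)

    bg_ids = [f"snp{j:05d}" for j in range(m)]
    variants = pd.DataFrame({
        "id": [PROXY_ID, MODIFIER_ID] + bg_ids,
        "chrom": [MODIFIER_CHROM, MODIFIER_CHROM] + ["1"] * m,
        "pos": [PROXY_POS, MODIFIER_POS] + [1_000_000 + 500_000 * j for j in range(m)],
        "ref": "G",
        "alt": "A",
        "qual": 1.0,
        "eaf": np.concatenate([[freqs[haps[:, 0] == 1].sum(), freqs[haps[:, 1] == 1].sum()],
                               background_mafs]),
    })
    samples = np.array([f"I{i:06d}" for i in range(n)])
    return GenotypePanel(samples=samples, variants=variants, dosages=dosages,
                         modifier=modifier, phased=phased)


def _covariates(n, rng) -> pd.DataFrame:
    cov = {"age": rng.normal(55.0, 10.0, size=n),
           "sex": rng.integers(0, 2, size=n).astype(float)}
    for i in range(1, 11):
        cov[f"PC{i}"] = rng.standard_normal(n)
    return pd.DataFrame(cov)


def _linear_predictor(panel, beta0, beta_mod, beta_snp, beta_int, gamma_cov, cov):
    lp = np.full(panel.n_samples, float(beta0))
    lp += beta_mod * panel.modifier
    for vid, b in beta_snp.items():
        lp += b * panel.dosage(vid)
    for vid, b in beta_int.items():
        lp += b * panel.dosage(vid) * panel.modifier
    for name, g in gamma_cov.items():
        lp += g * cov[name].to_numpy()
    return lp


def simulate_quantitative(panel: GenotypePanel, spec: EffectSpec, seed: int,
                          cov: pd.DataFrame | None = None) -> PhenotypeTable:
    """Left-censored log-normal daily alcohol intake plus covariates."""
    rng = np.random.default_rng(seed)
    if cov is None:
        cov = _covariates(panel.n_samples, rng)
    lp = _linear_predictor(panel, spec.beta0, spec.beta_mod, spec.beta_snp,
                           spec.beta_int, spec.gamma_cov, cov)
    ystar = lp + rng.normal(0.0, spec.sigma, size=panel.n_samples)
    raw = np.maximum(0.0, np.exp2(ystar) - 1.0)
    df = cov.copy()
    df["intake_gday"] = raw
    df["log_intake"] = np.log2(raw + 1.0)
    return PhenotypeTable(data=df)


def simulate_binary(panel: GenotypePanel, spec: EffectSpec, kind: str, seed: int,
                    case_control_ratio: float | None = None,
                    cov: pd.DataFrame | None = None):
    """Bernoulli outcome from the logistic linear predictor.

    ``kind='drinking_status'`` reads the EffectSpec's main fields on the
    logit scale; ``kind='disease'`` reads ``spec.disease_alpha`` and
    optionally downsamples controls to ``case_control_ratio`` controls per
    case, recording the control sampling fraction.

    Returns a PhenotypeTable; for downsampled designs the panel must be
    subset with the returned ``keep_mask`` (second return value when
    downsampling is requested).
    """
    rng = np.random.default_rng(seed)
    if cov is None:
        cov = _covariates(panel.n_samples, rng)
    if kind == "drinking_status":
        lp = _linear_predictor(panel, spec.beta0, spec.beta_mod, spec.beta_snp,
                               spec.beta_int, spec.gamma_cov, cov)
        col = "drinking_status"
    elif kind == "disease":
        a = spec.disease_alpha
        lp = _linear_predictor(panel, a.get("intercept", 0.0), a.get("beta_mod", 0.0),
                               a.get("beta_snp", {}), a.get("beta_int", {}),
                               a.get("gamma_cov", {}), cov)
        col = "case_status"
    else:
        raise ValueError(f"unknown outcome kind {kind!r}")
    y = rng.binomial(1, expit(lp))
    df = cov.copy()
    df[col] = y
    pheno = PhenotypeTable(data=df)
    if case_control_ratio is None or kind != "disease":
        return pheno
    cases = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y == 0)
    n_keep = int(round(case_control_ratio * len(cases)))
    if n_keep > len(controls):
        raise ValueError(
            f"ratio {case_control_ratio} needs {n_keep} controls but only {len(controls)} simulated")
    kept = rng.choice(controls, size=n_keep, replace=False)
    keep_mask = np.zeros(len(y), dtype=bool)
    keep_mask[cases] = True
    keep_mask[kept] = True
    sub = pheno.subset(keep_mask)
    sub.sampling_fraction = n_keep / len(controls)
    return sub, keep_mask


def _perturb_effects(spec: EffectSpec, tau2: float, rng) -> EffectSpec:
    """Per-cohort effect sizes: beta + Normal(0, tau2) on every genetic effect."""
    if tau2 == 0:
        return spec
    sd = np.sqrt(tau2)
    return EffectSpec(
        beta0=spec.beta0,
        beta_mod=spec.beta_mod + rng.normal(0, sd),
        beta_snp={k: v + rng.normal(0, sd) for k, v in spec.beta_snp.items()},
        beta_int={k: v + rng.normal(0, sd) for k, v in spec.beta_int.items()},
        gamma_cov=dict(spec.gamma_cov),
        sigma=spec.sigma,
        disease_alpha=dict(spec.disease_alpha),
    )


def simulate_multi_cohort(config: SimConfig, drinking: bool = False):
    """Generate the per-cohort (panel, phenotype) pairs.

    The variant map (positions and background MAFs) is shared across
    cohorts; per-cohort genetic effect sizes are beta + Normal(0, tau2).
    One global seed; per-cohort streams are spawned deterministically.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_cohorts + 1)
    maf_rng = np.random.default_rng(children[0])
    background_mafs = _draw_background_mafs(config, maf_rng)
    out = []
    for size, child in zip(config.cohort_sizes, children[1:]):
        rng = np.random.default_rng(child)
        panel = simulate_panel(config, n=size, rng=rng, background_mafs=background_mafs)
        spec_c = _perturb_effects(config.effects, config.tau2, rng)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        pheno = simulate_quantitative(panel, spec_c, seed=sub_seed)
        if drinking:
            dr = simulate_binary(panel, spec_c, "drinking_status", seed=sub_seed + 1,
                                 cov=pheno.data[[c for c in pheno.data
                                                 if c.startswith(("age", "sex", "PC"))]])
            pheno.data["drinking_status"] = dr.data["drinking_status"]
        out.append((panel, pheno))
    return out
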