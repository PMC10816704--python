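"""End-to-end pipeline compositions.

These orchestrate the generator and the analysis stages into the study's
standard experiments: the proxy-SNP sign-flip demonstration, null
calibration scans, the additive-interaction (RERI) case-control analysis,
and the stratified-versus-combined polygenic-score comparison. The CLI
subcommands mirror these compositions; tests and the reproduction script
drive them directly.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import assoc, interact_epi, ldhap, prs
from .data import GenotypePanel, PhenotypeTable
from .synthdata import (MODIFIER_ID, PROXY_ID, EffectSpec, SimConfig,
                        simulate_panel, simulate_quantitative)


def _spawn_seeds(seed: int, k: int) -> list[int]:
    return [int(c.generate_state(1)[0] >> 1) for c in np.random.SeedSequence(seed).spawn(k)]


def sign_flip_experiment(seed: int, n: int = 30_000,
                         proxy_beta: float = -0.2, mod_beta: float = -2.0) -> dict:
    """Reproduce the proxy-variant sign flip on the three-haplotype region.

    A proxy variant rides exclusively on the modifier's wild-type
    haplotype and carries a small negative within-stratum effect; the
    modifier itself has a large negative effect. Unstratified and
    GA-stratified scans are run, and the region's haplotypes are
    re-estimated by EM from the unphased genotypes.
    """
    spec = EffectSpec(beta0=3.0, beta_mod=mod_beta, sigma=1.5,
                      beta_snp={PROXY_ID: proxy_beta}, gamma_cov={})
    cfg = SimConfig(seed=seed, cohort_sizes=(n,), n_background_snps=2, effects=spec)
    s1, s2 = _spawn_seeds(seed, 2)
    panel = simulate_panel(cfg, n=n, rng=np.random.default_rng(s1))
    pheno = simulate_quantitative(panel, spec, seed=s2)
    unstrat = assoc.scan_linear(panel, pheno).set_index("variant_id")
    ga = assoc.scan_linear(panel, pheno, stratum="GA").set_index("variant_id")
    G = np.round(panel.dosages[:, :2]).astype(int)
    table = ldhap.em_haplotypes(G, allele_labels=[("G", "A"), ("G", "A")])
    observed = [h for h in ("G-G", "A-G", "G-A") if h in table.freqs]
    return {
        "beta_unstratified": float(unstrat.loc[PROXY_ID, "beta"]),
        "beta_ga": float(ga.loc[PROXY_ID, "beta"]),
        "absent_haplotype_freq": float(table.freqs.get("A-A", 0.0)),
        "explained_fraction": ldhap.explained_fraction(table, observed),
        "proxy_modifier_r2": ldhap.ld_pair(panel.dosages[:, 0], panel.dosages[:, 1],
                                           phased=False).r2,
        "proxy_modifier_dprime": ldhap.ld_pair(panel.dosages[:, 0], panel.dosages[:, 1],
                                               phased=False).Dprime,
    }


def null_scan_lambdas(seed: int, n_individuals: int = 400,
                      n_variants: int = 50_000) -> dict:
    """Genomic inflation of vectorized null scans: 1-df marginal and 2-df
    joint (main + interaction) statistics."""
    from . import _stats, meta
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(0.1, 0.5, n_variants)
    G = rng.binomial(2, mafs, (n_individuals, n_variants)).astype(float)
    mod = rng.binomial(1, 0.28, n_individuals).astype(float)
    y = rng.normal(0.0, 1.0, n_individuals)
    C = np.ones((n_individuals, 1))
    beta, se, lp, _ = _stats.ols_scan(y, G, C)
    lam1 = meta.genomic_inflation((beta / se) ** 2, df=1)
    res = _stats.ols_scan_interaction(y, G, mod, C)
    lam2 = meta.genomic_inflation(res["chi2_2df"], df=2)
    return {"lambda_1df": lam1, "lambda_2df": lam2}


def _case_control_panel(rng, n, f_snp=0.3, f_mod=0.25):
    g = rng.binomial(2, f_snp, n).astype(float)
    mod = rng.binomial(1, f_mod, n)
    variants = pd.DataFrame({"id": ["snp"], "chrom": "1", "pos": [1_000_000],
                             "ref": "G", "alt": "A", "qual": 1.0,
                             "eaf": [g.mean() / 2]})
    panel = GenotypePanel(samples=np.array([f"i{i}" for i in range(n)]),
                          variants=variants, dosages=g[:, None], modifier=mod)
    return panel, g, mod


def reri_additive_null_replicate(seed: int, n: int = 40_000, p0: float = 0.01,
                                 rr_snp: float = 1.5, rr_mod: float = 2.0):
    """One replicate under additivity of excess risks.

    Disease risk is p0 * (1 + (rr_snp - 1) g + (rr_mod - 1) m): the joint
    relative risk is the sum of the excess relative risks, so the true
    RERI is 0 (up to the rare-disease OR/RR approximation). Returns the
    fitted RERIResult.
    """
    rng = np.random.default_rng(seed)
    panel, g, mod = _case_control_panel(rng, n)
    risk = p0 * (1 + (rr_snp - 1) * g + (rr_mod - 1) * mod)
    y = rng.binomial(1, np.clip(risk, 0, 1))
    pheno = PhenotypeTable(data=pd.DataFrame({"case_status": y}))
    fit = interact_epi.fit_study_interaction(panel, pheno, "snp", covariates=())
    return interact_epi.reri(fit.beta, fit.cov)


def reri_interaction_replicate(seed: int, n: int = 200_000, b_snp: float = 0.3,
                               b_mod: float = 0.5, b_int: float = np.log(2.0),
                               intercept: float = -5.0,
                               case_control_ratio: float | None = None):
    """One replicate with a true multiplicative interaction on the logit
    scale (which implies positive additive interaction for positive
    effects); optional 1:k control subsampling before fitting."""
    from scipy.special import expit
    rng = np.random.default_rng(seed)
    panel, g, mod = _case_control_panel(rng, n)
    p = expit(intercept + b_snp * g + b_mod * mod + b_int * g * mod)
    y = rng.binomial(1, p)
    pheno = PhenotypeTable(data=pd.DataFrame({"case_status": y}))
    if case_control_ratio is not None:
        pheno, mask = interact_epi.subsample_controls(pheno, case_control_ratio,
                                                      seed=seed + 1)
        panel = panel.subset_samples(mask)
    fit = interact_epi.fit_study_interaction(panel, pheno, "snp", covariates=())
    return interact_epi.reri(fit.beta, fit.cov)


def combined_prs_experiment(seed: int, interaction_rich: bool = True,
                            n_discovery: int = 8_000, n_score: int = 4_500,
                            n_causal: int = 20, n_background: int = 200) -> dict:
    """Discovery GWAS -> three C+T scores -> combined score, on independent
    discovery and scoring cohorts.

    ``interaction_rich=True`` plants stratum-dependent effects: each causal
    SNP's effect changes sign between GG and GA carriers, and the modifier
    itself is strongly protective — the architecture in which a
    main-effects-only score fails while the combined score gains. With
    ``interaction_rich=False`` all effects are shared and the modifier is
    null, so the unstratified score should win.

    Returns validation R2 (%) for the combined score, the modifier alone,
    and the unstratified PRS, all on validation GG/GA individuals.
    """
    ids = [f"snp{j:05d}" for j in range(n_causal)]
    sign = np.resize([1.0, -1.0], n_causal)
    causal = {v: 0.25 * s for v, s in zip(ids, sign)}
    if interaction_rich:
        inter = {v: -0.5 * s for v, s in zip(ids, sign)}
        beta_mod = -1.8
    else:
        inter = {}
        beta_mod = 0.0
    spec = EffectSpec(beta0=3.0, beta_mod=beta_mod, sigma=2.0,
                      beta_snp=causal, beta_int=inter, gamma_cov={"sex": 1.0})
    cfg = SimConfig(seed=seed, cohort_sizes=(n_discovery,),
                    n_background_snps=n_background, maf_range=(0.2, 0.5),
                    effects=spec)
    s1, s2, s3, s4 = _spawn_seeds(seed, 4)
    disc = simulate_panel(cfg, n=n_discovery, rng=np.random.default_rng(s1))
    disc_ph = simulate_quantitative(disc, spec, seed=s2)
    sums = {}
    for src, stratum in (("unstratified", "all"), ("GG", "GG"), ("GA", "GA")):
        rec = assoc.scan_linear(disc, disc_ph, stratum=stratum)
        # the modifier is directly genotyped, not scored; it enters only
        # through stratification and the combined model
        sums[src] = rec[rec["variant_id"] != MODIFIER_ID].reset_index(drop=True)

    panel = simulate_panel(cfg, n=n_score, rng=np.random.default_rng(s3))
    pheno = simulate_quantitative(panel, spec, seed=s4)
    resid = prs.residualize_phenotype(pheno)
    tgt, _ = prs.split_sample(panel.n_samples, seed=seed)
    tm = np.zeros(panel.n_samples, bool)
    tm[tgt] = True
    t_panel, v_panel = panel.subset_samples(tm), panel.subset_samples(~tm)
    t_res, v_res = resid[tm], resid[~tm]

    models = {}
    for src in ("unstratified", "GG", "GA"):
        if src == "unstratified":
            tp, tr = t_panel, t_res
        else:
            m = t_panel.modifier == (0 if src == "GG" else 1)
            tp, tr = t_panel.subset_samples(m), t_res[m]
        models[src] = prs.build_ct_prs(sums[src], tp, tr, source=src)

    t_keep = t_panel.modifier < 2
    t_sub = t_panel.subset_samples(t_keep)
    combined = prs.fit_combined(t_sub.modifier, prs.score(t_sub, models["GG"]),
                                prs.score(t_sub, models["GA"]), t_res[t_keep])
    v_keep = v_panel.modifier < 2
    v_sub = v_panel.subset_samples(v_keep)
    v_sub_res = v_res[v_keep]
    pred = combined.predict(v_sub.modifier, prs.score(v_sub, models["GG"]),
                            prs.score(v_sub, models["GA"]))
    return {
        "r2_combined": prs.evaluate_r2(pred, v_sub_res),
        "r2_modifier_alone": prs.evaluate_r2(v_sub.modifier, v_sub_res),
        "r2_unstratified_prs": prs.evaluate_r2(prs.score(v_sub, models["unstratified"]),
                                               v_sub_res),
    }
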