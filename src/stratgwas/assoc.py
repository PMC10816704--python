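"""Per-variant association scans.

Three designs are supported, mirroring the analysis plan of a
genotype-stratified GWAS against a strong effect-modifier variant:

* unstratified and modifier-genotype-stratified scans (``stratum`` of
  ``all``, ``GG`` or ``GA``; variant-homozygote-only analysis is not
  offered),
* interaction scans fitting ``pheno ~ covariates + modifier + g + g*modifier``
  with the modifier coded GG = 0 / GA = 1 and AA carriers excluded, and
* Firth penalized logistic regression for heavily unbalanced case-control
  designs.

Effect-allele bookkeeping follows the METAL convention: the effect allele
is always ALT and the reported EAF is the ALT-allele frequency. All
p-values are stored as log10 so that extreme statistics never underflow.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import _stats
from .data import DEFAULT_COVARIATES, GenotypePanel, PhenotypeTable, stratum_mask

logger = logging.getLogger(__name__)

OUTCOME_COLUMNS = {
    "quantitative": "log_intake",
    "drinking_status": "drinking_status",
    "case": "case_status",
}


def transform_phenotype(raw_intake):
    """log2(grams/day + 1) transform of daily alcohol intake."""
    raw = np.asarray(raw_intake, dtype=float)
    if np.any(raw < 0):
        raise ValueError("raw intake must be non-negative")
    return np.log2(raw + 1.0)


def filter_variants(panel: GenotypePanel, quality_threshold: float = 0.3,
                    maf_threshold: float = 0.01) -> GenotypePanel:
    """Post-imputation QC: drop variants with quality < threshold or
    MAF < threshold (boundaries retained: the exclusion rules are strict
    inequalities)."""
    for thr in (quality_threshold, maf_threshold):
        if not (0 <= thr <= 1):
            raise ValueError("thresholds must lie in [0, 1]")
    qual = panel.variants["qual"].to_numpy(dtype=float)
    maf = panel.maf()
    keep = (qual >= quality_threshold) & (maf >= maf_threshold)
    logger.info("filter_variants: %d of %d retained (quality>=%g, MAF>=%g)",
                keep.sum(), len(keep), quality_threshold, maf_threshold)
    return panel.subset_variants(keep)


def _base_records(panel: GenotypePanel, n: int, stratum: str, model: str, study):
    v = panel.variants
    return pd.DataFrame({
        "variant_id": v["id"].to_numpy(),
        "chrom": v["chrom"].to_numpy(),
        "pos": v["pos"].to_numpy(),
        "effect_allele": v["alt"].to_numpy(),
        "other_allele": v["ref"].to_numpy(),
        "eaf": panel.dosages.mean(axis=0) / 2.0,
        "n": n,
        "stratum": stratum,
        "model": model,
        "study": study,
    })


def _select(panel, pheno, outcome, stratum):
    col = OUTCOME_COLUMNS[outcome]
    y_all = pheno.data[col].to_numpy(dtype=float)
    mask = stratum_mask(panel, stratum) & ~np.isnan(y_all)
    return panel.subset_samples(mask), pheno.subset(mask), y_all[mask]


def scan_linear(panel: GenotypePanel, pheno: PhenotypeTable, stratum: str = "all",
                covariates=DEFAULT_COVARIATES, study=None) -> pd.DataFrame:
    """Per-variant OLS of log intake on ALT dosage plus covariates.

    Monomorphic-in-stratum variants are flagged (``monomorphic`` column),
    not errors, so multi-stratum scans proceed.
    """
    sub, ph, y = _select(panel, pheno, "quantitative", stratum)
    C, names = ph.covariate_matrix(covariates)
    _stats.check_full_rank(C, names)
    beta, se, log10_p, dof = _stats.ols_scan(y, sub.dosages, C)
    rec = _base_records(sub, len(y), stratum, "linear", study)
    rec["beta"] = beta
    rec["se"] = se
    rec["log10_p"] = log10_p
    rec["monomorphic"] = np.isnan(beta)
    return rec


def scan_logistic(panel: GenotypePanel, pheno: PhenotypeTable,
                  outcome: str = "drinking_status", stratum: str = "all",
                  covariates=DEFAULT_COVARIATES, study=None) -> pd.DataFrame:
    """Per-variant maximum-likelihood logistic regression (Wald inference).

    Non-converged or separated fits are flagged (``flag`` column suggests
    the Firth path) rather than raised.
    """
    if outcome not in ("drinking_status", "case"):
        raise ValueError("outcome must be 'drinking_status' or 'case'")
    sub, ph, y = _select(panel, pheno, outcome, stratum)
    if y.min() == y.max():
        raise ValueError("outcome has no variation")
    C, names = ph.covariate_matrix(covariates)
    _stats.check_full_rank(C, names)
    m = sub.n_variants
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    flags = np.array([""] * m, dtype=object)
    for j in range(m):
        g = sub.dosages[:, j]
        if g.std() == 0:
            flags[j] = "monomorphic"
            continue
        X = np.column_stack([C, g])
        try:
            fit = _stats.logistic_irls(X, y)
        except ValueError:
            flags[j] = "degenerate"
            continue
        if fit.separated:
            flags[j] = "separation; consider Firth"
        elif not fit.converged:
            flags[j] = "non-converged; consider Firth"
        beta[j] = fit.beta[-1]
        se[j] = fit.se[-1]
    rec = _base_records(sub, len(y), stratum, "logistic", study)
    rec["beta"] = beta
    rec["se"] = se
    rec["log10_p"] = _stats.log10_sf_norm_twosided(beta / se)
    rec["flag"] = flags
    return rec


def scan_interaction(panel: GenotypePanel, pheno: PhenotypeTable,
                     outcome_kind: str = "quantitative",
                     covariates=DEFAULT_COVARIATES, study=None,
                     robust: bool = False) -> pd.DataFrame:
    """Joint per-variant fit of the SNP main effect and SNP x modifier
    interaction, with their full covariance.

    AA carriers are excluded and the modifier is coded GG = 0 / GA = 1
    before fitting. The linear path is vectorized; the logistic path fits
    per variant by IRLS. ``robust=True`` swaps in a sandwich covariance.
    """
    keep = panel.modifier < 2
    sub_all = panel.subset_samples(keep)
    ph_all = pheno.subset(keep)
    if not np.any(sub_all.modifier == 1):
        raise ValueError("no GA individuals: interaction is inestimable")
    col = OUTCOME_COLUMNS[outcome_kind]
    y_all = ph_all.data[col].to_numpy(dtype=float)
    ok = ~np.isnan(y_all)
    sub = sub_all.subset_samples(ok)
    ph = ph_all.subset(ok)
    y = y_all[ok]
    mod = sub.modifier.astype(float)
    C, names = ph.covariate_matrix(covariates)
    _stats.check_full_rank(np.column_stack([C, mod]), names + ["modifier"])

    model = "linear_interaction" if outcome_kind == "quantitative" else "logistic_interaction"
    rec = _base_records(sub, len(y), "all", model, study)
    if outcome_kind == "quantitative" and not robust:
        res = _stats.ols_scan_interaction(y, sub.dosages, mod, C)
        rec["beta"] = res["beta_snp"]
        rec["se"] = res["se_snp"]
        rec["beta_int"] = res["beta_int"]
        rec["se_int"] = res["se_int"]
        rec["cov_snp_int"] = res["cov_snp_int"]
        rec["log10_p"] = res["log10_p_snp"]
        rec["log10_p_int"] = res["log10_p_int"]
        rec["chi2_2df"] = res["chi2_2df"]
        return rec

    m = sub.n_variants
    out = {k: np.full(m, np.nan) for k in
           ("beta", "se", "beta_int", "se_int", "cov_snp_int", "chi2_2df")}
    for j in range(m):
        g = sub.dosages[:, j]
        if g.std() == 0:
            continue
        X = np.column_stack([C, mod, g, g * mod])
        if outcome_kind == "quantitative":
            coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            dof = len(y) - X.shape[1]
            XtX_inv = np.linalg.inv(X.T @ X)
            if robust:
                meat = X.T @ (X * (resid**2)[:, None])
                cov = XtX_inv @ meat @ XtX_inv
            else:
                cov = XtX_inv * (resid @ resid / dof)
        else:
            try:
                fit = _stats.logistic_irls(X, y)
            except ValueError:
                continue
            coef = fit.beta
            cov = fit.cov
            if robust:
                p = 1.0 / (1.0 + np.exp(-(X @ coef)))
                meat = X.T @ (X * ((y - p) ** 2)[:, None])
                cov = fit.cov @ meat @ fit.cov
        i_g, i_gm = X.shape[1] - 2, X.shape[1] - 1
        out["beta"][j] = coef[i_g]
        out["beta_int"][j] = coef[i_gm]
        out["se"][j] = np.sqrt(cov[i_g, i_g])
        out["se_int"][j] = np.sqrt(cov[i_gm, i_gm])
        out["cov_snp_int"][j] = cov[i_g, i_gm]
        V = cov[np.ix_([i_g, i_gm], [i_g, i_gm])]
        b = coef[[i_g, i_gm]]
        try:
            out["chi2_2df"][j] = b @ np.linalg.solve(V, b)
        except np.linalg.LinAlgError:
            pass
    for k, v in out.items():
        rec[k] = v
    rec["log10_p"] = _stats.log10_sf_norm_twosided(rec["beta"] / rec["se"])
    rec["log10_p_int"] = _stats.log10_sf_norm_twosided(rec["beta_int"] / rec["se_int"])
    return rec


def fit_firth(panel: GenotypePanel, pheno: PhenotypeTable,
              covariates=DEFAULT_COVARIATES, stratum: str = "all",
              outcome: str = "case", study=None) -> pd.DataFrame:
    """Firth bias-reduced logistic scan; finite estimates under separation."""
    sub, ph, y = _select(panel, pheno, outcome, stratum)
    if y.min() == y.max():
        raise ValueError("outcome has no variation")
    C, names = ph.covariate_matrix(covariates)
    _stats.check_full_rank(C, names)
    m = sub.n_variants
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    for j in range(m):
        g = sub.dosages[:, j]
        if g.std() == 0:
            continue
        fit = _stats.firth_logistic(np.column_stack([C, g]), y)
        beta[j] = fit.beta[-1]
        se[j] = fit.se[-1]
    rec = _base_records(sub, len(y), stratum, "firth", study)
    rec["beta"] = beta
    rec["se"] = se
    rec["log10_p"] = _stats.log10_sf_norm_twosided(beta / se)
    return rec


def flip_alleles(records: pd.DataFrame, variant_ids) -> pd.DataFrame:
    """Re-express records with the other allele as effect allele:
    beta is negated, EAF maps to 1 - EAF, p-values unchanged."""
    rec = records.copy()
    m = rec["variant_id"].isin(set(variant_ids))
    rec.loc[m, ["effect_allele", "other_allele"]] = (
        rec.loc[m, ["other_allele", "effect_allele"]].to_numpy())
    rec.loc[m, "beta"] = -rec.loc[m, "beta"]
    rec.loc[m, "eaf"] = 1.0 - rec.loc[m, "eaf"]
    if "beta_int" in rec:
        rec.loc[m, "beta_int"] = -rec.loc[m, "beta_int"]
    return rec
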