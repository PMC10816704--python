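"""Case-control gene-gene interaction epidemiology.

Per-study logistic models with a SNP x modifier product term are pooled by
multivariate random-effects meta-analysis (maximum likelihood over an
unstructured between-study covariance), and additive interaction is
quantified by the relative excess risk due to interaction,

    RERI = exp(b_snp + b_mod + b_int) - exp(b_snp) - exp(b_mod) + 1,

with delta-method confidence intervals and Wald tests. Multiplicative
interaction is exp(b_int). Stratified odds ratios are pooled per stratum
by DerSimonian-Laird random effects. Two sensitivity tools mirror common
practice for extreme case:control imbalance: Firth penalized regression
and seeded 1:k control subsampling.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _stats, meta
from .data import DEFAULT_COVARIATES, GenotypePanel, PhenotypeTable

logger = logging.getLogger(__name__)

Z95 = 1.959964  # two-sided 95% normal quantile


@dataclass
class StudyFit:
    beta: np.ndarray          # (b_snp, b_mod, b_int)
    cov: np.ndarray           # 3x3
    n: int
    flag: str = ""


@dataclass
class RERIResult:
    beta: np.ndarray          # pooled (b_snp, b_mod, b_int)
    cov: np.ndarray           # pooled 3x3 covariance
    psi: np.ndarray | None    # between-study covariance (None for single fit)
    or_snp: float
    or_mod: float
    joint_or: float
    reri: float
    se: float
    ci: tuple
    log10_p: float
    mult_or: float
    mult_ci: tuple
    mult_log10_p: float
    suggestive: bool          # CI excludes 0
    bonferroni_significant: bool

    @property
    def decomposition(self):
        """Stacked-bar decomposition: jointOR = (OR_snp-1) + (OR_mod-1) + RERI + 1."""
        return {"excess_snp": self.or_snp - 1.0, "excess_mod": self.or_mod - 1.0,
                "reri": self.reri, "baseline": 1.0}


def fit_study_interaction(panel: GenotypePanel, pheno: PhenotypeTable, snp_id: str,
                          covariates=DEFAULT_COVARIATES, coding: str = "dosage",
                          firth_on_separation: bool = True) -> StudyFit:
    """Per-study logistic fit of case status on SNP, modifier (GG=0/GA=1,
    AA excluded), their product, and covariates.

    ``coding='hardcall'`` rounds dosages to 0/1/2 before fitting (the
    direct-genotyping convention); ``'dosage'`` uses them as is. Perfect
    separation triggers a Firth fallback (finite estimates) with a flag.
    """
    keep = panel.modifier < 2
    sub = panel.subset_samples(keep)
    ph = pheno.subset(keep)
    y = ph.data["case_status"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("case status has no variation")
    g = sub.dosage(snp_id)
    if coding == "hardcall":
        g = np.round(g)
    elif coding != "dosage":
        raise ValueError("coding must be 'dosage' or 'hardcall'")
    mod = sub.modifier.astype(float)
    if mod.max() == 0:
        raise ValueError("no GA individuals in study")
    C, names = ph.covariate_matrix(covariates)
    _stats.check_full_rank(C, names)
    X = np.column_stack([C, g, mod, g * mod])
    idx = [X.shape[1] - 3, X.shape[1] - 2, X.shape[1] - 1]
    fit = _stats.logistic_irls(X, y)
    flag = ""
    if fit.separated or not fit.converged:
        flag = "separation; Firth fallback" if fit.separated else "non-converged; Firth fallback"
        if firth_on_separation:
            fit = _stats.firth_logistic(X, y)
        else:
            logger.warning("fit_study_interaction: %s", flag)
    b = fit.beta[idx]
    V = fit.cov[np.ix_(idx, idx)]
    return StudyFit(beta=b, cov=V, n=len(y), flag=flag)


def _nll_mv(chol_params, bs, Vs, dim, reml=False):
    L = np.zeros((dim, dim))
    tril = np.tril_indices(dim)
    L[tril] = chol_params
    Psi = L @ L.T
    precision = np.zeros((dim, dim))
    weighted = np.zeros(dim)
    parts = []
    for b, V in zip(bs, Vs):
        S = V + Psi
        try:
            Sinv = np.linalg.inv(S)
        except np.linalg.LinAlgError:
            return 1e12
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            return 1e12
        precision += Sinv
        weighted += Sinv @ b
        parts.append((b, Sinv, logdet))
    pooled = np.linalg.solve(precision, weighted)
    nll = 0.0
    for b, Sinv, logdet in parts:
        r = b - pooled
        nll += 0.5 * (logdet + r @ Sinv @ r)
    if reml:
        sign, logdet_p = np.linalg.slogdet(precision)
        nll += 0.5 * logdet_p
    return nll


def mv_meta_ml(fits: list[StudyFit], max_iter: int = 500, method: str = "ml"):
    """Multivariate random-effects pooling by likelihood maximization.

    The marginal model is b_i ~ Normal(b, V_i + Psi) with Psi unstructured
    positive semidefinite (Cholesky-parameterized). ``method='reml'``
    maximizes the restricted likelihood instead, which removes most of the
    small-k downward bias of the ML Psi estimate. Returns
    (pooled_beta, pooled_cov, Psi). A single study is passed through with
    Psi = 0; optimizer failure falls back to fixed effects with a warning.
    """
    if len(fits) == 1:
        f = fits[0]
        return f.beta.copy(), f.cov.copy(), np.zeros_like(f.cov)
    reml = method == "reml"
    bs = [f.beta for f in fits]
    Vs = [f.cov for f in fits]
    dim = len(bs[0])
    tril = np.tril_indices(dim)
    x0 = np.zeros(len(tril[0]))
    res = optimize.minimize(_nll_mv, x0, args=(bs, Vs, dim, reml), method="Nelder-Mead",
                            options={"maxiter": max_iter * len(x0), "xatol": 1e-6,
                                     "fatol": 1e-9})
    if not res.success and res.fun >= _nll_mv(x0, bs, Vs, dim, reml) - 1e-9:
        logger.warning("mv_meta_ml: ML did not improve; falling back to fixed effects")
        res_x = x0
    else:
        res_x = res.x
    L = np.zeros((dim, dim))
    L[tril] = res_x
    Psi = L @ L.T
    precision = np.zeros((dim, dim))
    weighted = np.zeros(dim)
    for b, V in zip(bs, Vs):
        Sinv = np.linalg.inv(V + Psi)
        precision += Sinv
        weighted += Sinv @ b
    Sigma = np.linalg.inv(precision)
    pooled = Sigma @ weighted
    return pooled, Sigma, Psi


def reri(beta, Sigma, n_tests: int = 8) -> RERIResult:
    """RERI with delta-method CI from the pooled (b_snp, b_mod, b_int).

    The gradient of RERI is (e^s - e^{b1}, e^s - e^{b2}, e^s) with
    s = b1 + b2 + b3; SE = sqrt(g' Sigma g); the 95% CI is RERI +- 1.96 SE.
    Suggestive significance means the CI excludes 0; the Bonferroni
    threshold is 0.05 / n_tests.
    """
    b = np.asarray(beta, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    eig = np.linalg.eigvalsh((Sigma + Sigma.T) / 2)
    if eig.min() < -1e-8:
        raise ValueError("covariance matrix is not positive semidefinite")
    s = b.sum()
    val = np.exp(s) - np.exp(b[0]) - np.exp(b[1]) + 1.0
    g = np.array([np.exp(s) - np.exp(b[0]), np.exp(s) - np.exp(b[1]), np.exp(s)])
    se = float(np.sqrt(g @ Sigma @ g))
    ci = (val - Z95 * se, val + Z95 * se)
    z = val / se if se > 0 else np.inf
    lp = float(_stats.log10_sf_norm_twosided(z))
    m_or, m_ci, m_lp = multiplicative_interaction(b, Sigma)
    p = 10.0 ** max(lp, -300)
    return RERIResult(
        beta=b, cov=Sigma, psi=None,
        or_snp=float(np.exp(b[0])), or_mod=float(np.exp(b[1])),
        joint_or=float(np.exp(s)),
        reri=float(val), se=se, ci=ci, log10_p=lp,
        mult_or=m_or, mult_ci=m_ci, mult_log10_p=m_lp,
        suggestive=not (ci[0] <= 0.0 <= ci[1]),
        bonferroni_significant=p < 0.05 / n_tests,
    )


def multiplicative_interaction(beta, Sigma):
    """Summary interaction OR = exp(b_int) with Wald CI on the log scale."""
    b = np.asarray(beta, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    se = np.sqrt(Sigma[2, 2])
    or_int = float(np.exp(b[2]))
    ci = (float(np.exp(b[2] - Z95 * se)), float(np.exp(b[2] + Z95 * se)))
    lp = float(_stats.log10_sf_norm_twosided(b[2] / se)) if se > 0 else -np.inf
    return or_int, ci, lp


def stratified_or_meta(study_records: pd.DataFrame) -> pd.DataFrame:
    """Pool per-study log-ORs per stratum by random effects.

    Input columns: variant_id, stratum, beta (log-OR), se, n, study.
    Output one row per (variant, stratum) with pooled OR, CI, Q and I2.
    """
    rows = []
    for (vid, stratum), grp in study_records.groupby(["variant_id", "stratum"], sort=False):
        pooled = meta.random_effects_meta(grp.assign(variant_id=vid))
        r = pooled.iloc[0]
        rows.append({
            "variant_id": vid, "stratum": stratum,
            "or": float(np.exp(r["beta"])),
            "ci_low": float(np.exp(r["beta"] - Z95 * r["se"])),
            "ci_high": float(np.exp(r["beta"] + Z95 * r["se"])),
            "log10_p": r["log10_p"], "k": r["k"], "Q": r["Q"], "i2": r["i2"],
        })
    return pd.DataFrame(rows)


def subsample_controls(pheno: PhenotypeTable, ratio: float, seed: int):
    """Seeded 1:ratio control subsampling without replacement.

    Returns (subset PhenotypeTable, boolean keep mask over the input rows).
    """
    y = pheno.data["case_status"].to_numpy(dtype=float)
    cases = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y == 0)
    n_keep = int(round(ratio * len(cases)))
    if n_keep > len(controls):
        raise ValueError(f"need {n_keep} controls, only {len(controls)} available")
    rng = np.random.default_rng(seed)
    kept = rng.choice(controls, size=n_keep, replace=False)
    mask = np.zeros(len(y), dtype=bool)
    mask[cases] = True
    mask[kept] = True
    sub = pheno.subset(mask)
    sub.sampling_fraction = n_keep / len(controls)
    return sub, mask
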