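"""Joint meta-analysis (JMA) of SNP main and SNP x modifier interaction
effects.

Each study contributes a bivariate estimate (beta_snp, beta_int) with its
full 2x2 covariance. Pooling is fixed-effects multivariate:

    V_pooled = (sum_i V_i^{-1})^{-1},   b_pooled = V_pooled sum_i V_i^{-1} b_i

and the joint test is the 2-df Wald statistic b' V^{-1} b. The ``cor``
diagnostic is the correlation of the pooled estimates,
IntCov / (StdErr x IntStdErr). QC removes variants with any
contributing-study MAF < 0.05, per-coefficient heterogeneity P < 0.001,
or cor < 0.7 (in that order, with counts logged so the filter funnel is
auditable). Genomic control uses the 2-df reference median 2 ln 2 and
divides the chi-square statistics by lambda when lambda > 1.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import _stats

logger = logging.getLogger(__name__)

REQUIRED = ("variant_id", "beta", "se", "beta_int", "se_int", "cov_snp_int")


def joint_meta(records: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effects multivariate pooling with 2-df Wald test per variant.

    Input rows are per-study bivariate records (columns ``beta``, ``se``,
    ``beta_int``, ``se_int``, ``cov_snp_int``, optionally ``n``).
    """
    for c in REQUIRED:
        if c not in records:
            raise ValueError(f"missing column {c!r}")
    rows = []
    for vid, grp in records.groupby("variant_id", sort=False):
        grp = grp.dropna(subset=["beta", "se", "beta_int", "se_int", "cov_snp_int"])
        if len(grp) == 0:
            continue
        bs = grp[["beta", "beta_int"]].to_numpy(dtype=float)
        Vs = np.empty((len(grp), 2, 2))
        Vs[:, 0, 0] = grp["se"] ** 2
        Vs[:, 1, 1] = grp["se_int"] ** 2
        Vs[:, 0, 1] = Vs[:, 1, 0] = grp["cov_snp_int"]
        precision = np.zeros((2, 2))
        weighted = np.zeros(2)
        for b, V in zip(bs, Vs):
            if np.linalg.det(V) <= 1e-10 * V[0, 0] * V[1, 1]:
                raise ValueError(f"singular study covariance for variant {vid!r}")
            Vinv = np.linalg.inv(V)
            precision += Vinv
            weighted += Vinv @ b
        Vp = np.linalg.inv(precision)
        bp = Vp @ weighted
        chi2 = float(bp @ precision @ bp)
        cor = float(Vp[0, 1] / np.sqrt(Vp[0, 0] * Vp[1, 1]))
        # per-coefficient Cochran Q against the pooled values
        k = len(grp)
        het = {}
        for name, col_b, col_se, pooled in (
                ("snp", "beta", "se", bp[0]), ("int", "beta_int", "se_int", bp[1])):
            w = 1.0 / grp[col_se].to_numpy(dtype=float) ** 2
            Q = float((w * (grp[col_b].to_numpy(dtype=float) - pooled) ** 2).sum())
            het[f"het_q_{name}"] = Q
            het[f"log10_het_p_{name}"] = (
                float(_stats.log10_sf_chi2(Q, k - 1)) if k > 1 else np.nan)
        rows.append({
            "variant_id": vid,
            "beta_snp": bp[0], "beta_int": bp[1],
            "se_snp": float(np.sqrt(Vp[0, 0])), "se_int": float(np.sqrt(Vp[1, 1])),
            "cov_snp_int": float(Vp[0, 1]),
            "chi2_2df": chi2,
            "log10_joint_p": float(_stats.log10_sf_chi2(chi2, 2)),
            "cor": cor,
            "k": k,
            "n": int(grp["n"].sum()) if "n" in grp else np.nan,
            **het,
        })
    return pd.DataFrame(rows)


def jma_qc(jma_records: pd.DataFrame, study_records: pd.DataFrame,
           maf_threshold: float = 0.05, het_p_threshold: float = 1e-3,
           cor_threshold: float = 0.7) -> pd.DataFrame:
    """Bespoke JMA QC funnel, applied in the order MAF -> heterogeneity -> cor.

    * drop variants with MAF < 0.05 in any contributing study,
    * drop variants with per-coefficient heterogeneity P < 0.001, and
    * drop variants with cor < 0.7 (boundary retained).

    ``study_records`` supplies per-study EAFs (columns ``variant_id``,
    ``eaf``). Counts at each step are logged.
    """
    rec = jma_records.copy()
    n0 = len(rec)
    min_maf = study_records.assign(
        maf=np.minimum(study_records["eaf"], 1.0 - study_records["eaf"])
    ).groupby("variant_id")["maf"].min()
    ok_maf = rec["variant_id"].map(min_maf).fillna(0.0) >= maf_threshold
    rec = rec.loc[ok_maf]
    logger.info("jma_qc: MAF filter kept %d of %d", len(rec), n0)
    n1 = len(rec)
    log10_thr = np.log10(het_p_threshold)
    het_ok = ~((rec["log10_het_p_snp"] < log10_thr) | (rec["log10_het_p_int"] < log10_thr))
    rec = rec.loc[het_ok.fillna(True)]
    logger.info("jma_qc: heterogeneity filter kept %d of %d", len(rec), n1)
    n2 = len(rec)
    rec = rec.loc[rec["cor"] >= cor_threshold]
    logger.info("jma_qc: cor filter kept %d of %d", len(rec), n2)
    return rec.reset_index(drop=True)


def gc_correct_2df(jma_records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """2-df genomic control: lambda = median(chi2) / (2 ln 2); when
    lambda > 1 every chi-square is divided by lambda and the joint p
    recomputed. lambda <= 1 leaves the statistics unchanged.
    """
    if len(jma_records) == 0:
        raise ValueError("no records to correct")
    if len(jma_records) < 100:
        logger.warning("gc_correct_2df: only %d variants; lambda is noisy", len(jma_records))
    lam = float(np.median(jma_records["chi2_2df"]) / _stats.CHI2_MEDIAN_2DF)
    rec = jma_records.copy()
    if lam > 1.0:
        rec["chi2_2df"] = rec["chi2_2df"] / lam
        rec["log10_joint_p"] = _stats.log10_sf_chi2(rec["chi2_2df"].to_numpy(), 2)
    rec["lambda_2df"] = lam
    return rec, lam
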