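"""Cross-study pooling of per-variant association records.

Implements the standard summary-statistics toolkit: inverse-variance
weighted fixed-effects meta-analysis with Cochran's Q and I-squared,
DerSimonian-Laird random-effects sensitivity analysis, the per-study
SE correction by a supplied LD-score-regression intercept, the
per-analysis-kind inclusion filters, and the genomic inflation factor.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import _stats

logger = logging.getLogger(__name__)

#: minimum total sample size by analysis kind (with k >= 3 studies)
INCLUSION_N_FLOOR = {"unstratified": 20_000, "interaction": 20_000, "stratified": 10_000}
MIN_STUDIES = 3


def correct_by_intercept(records: pd.DataFrame, intercept: float,
                         sqrt_convention: bool = False) -> pd.DataFrame:
    """Multiply every SE by the supplied intercept when it exceeds 1.

    The default multiplies by the intercept itself; ``sqrt_convention=True``
    multiplies by its square root instead (the alternative convention in
    the LD-score literature). p-values are recomputed.
    """
    if intercept <= 0:
        raise ValueError("intercept must be positive")
    if intercept <= 1.0:
        return records.copy()
    factor = np.sqrt(intercept) if sqrt_convention else intercept
    rec = records.copy()
    for se_col in ("se", "se_int"):
        if se_col in rec:
            rec[se_col] = rec[se_col] * factor
    rec["log10_p"] = _stats.log10_sf_norm_twosided(rec["beta"] / rec["se"])
    if "beta_int" in rec:
        rec["log10_p_int"] = _stats.log10_sf_norm_twosided(rec["beta_int"] / rec["se_int"])
        # covariance scales with both SEs
        if "cov_snp_int" in rec:
            rec["cov_snp_int"] = rec["cov_snp_int"] * factor**2
    return rec


def _pool_fixed(beta, se):
    w = 1.0 / se**2
    sw = w.sum()
    pooled = (w * beta).sum() / sw
    pooled_se = np.sqrt(1.0 / sw)
    Q = 0.0 if len(beta) == 1 else (w * (beta - pooled) ** 2).sum()
    return pooled, pooled_se, Q, w


def _meta_frame(rows):
    return pd.DataFrame(rows, columns=[
        "variant_id", "beta", "se", "log10_p", "k", "n", "Q", "df",
        "log10_het_p", "i2", "method", "tau2"])


def ivw_meta(records: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effects inverse-variance-weighted meta-analysis per variant.

    Variants present in only some studies are pooled over the contributing
    studies. I-squared is max(0, (Q - df)/Q) * 100, clipped to [0, 100].
    """
    if np.any(records["se"].to_numpy() <= 0):
        raise ValueError("all study SEs must be positive")
    rows = []
    for vid, grp in records.groupby("variant_id", sort=False):
        grp = grp.dropna(subset=["beta", "se"])
        if len(grp) == 0:
            continue
        beta = grp["beta"].to_numpy(dtype=float)
        se = grp["se"].to_numpy(dtype=float)
        pooled, pooled_se, Q, _ = _pool_fixed(beta, se)
        k = len(beta)
        df = k - 1
        i2 = 0.0 if Q <= df or Q == 0 else 100.0 * max(0.0, (Q - df) / Q)
        het_p = _stats.log10_sf_chi2(Q, df) if df > 0 else np.nan
        rows.append((vid, pooled, pooled_se,
                     float(_stats.log10_sf_norm_twosided(pooled / pooled_se)),
                     k, int(grp["n"].sum()), Q, df, het_p, min(i2, 100.0), "fixed", 0.0))
    return _meta_frame(rows)


def random_effects_meta(records: pd.DataFrame) -> pd.DataFrame:
    """DerSimonian-Laird random-effects meta-analysis per variant."""
    if np.any(records["se"].to_numpy() <= 0):
        raise ValueError("all study SEs must be positive")
    rows = []
    for vid, grp in records.groupby("variant_id", sort=False):
        grp = grp.dropna(subset=["beta", "se"])
        if len(grp) == 0:
            continue
        beta = grp["beta"].to_numpy(dtype=float)
        se = grp["se"].to_numpy(dtype=float)
        _, _, Q, w = _pool_fixed(beta, se)
        k = len(beta)
        df = k - 1
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (Q - df) / denom) if df > 0 and denom > 0 else 0.0
        ws = 1.0 / (se**2 + tau2)
        pooled = (ws * beta).sum() / ws.sum()
        pooled_se = np.sqrt(1.0 / ws.sum())
        i2 = 0.0 if Q <= df or Q == 0 else 100.0 * max(0.0, (Q - df) / Q)
        het_p = _stats.log10_sf_chi2(Q, df) if df > 0 else np.nan
        rows.append((vid, pooled, pooled_se,
                     float(_stats.log10_sf_norm_twosided(pooled / pooled_se)),
                     k, int(grp["n"].sum()), Q, df, het_p, min(i2, 100.0), "random", tau2))
    return _meta_frame(rows)


def inclusion_filter(meta_records: pd.DataFrame, analysis_kind: str) -> pd.DataFrame:
    """Keep variants with data from at least three studies and a total
    sample size at or above the kind-specific floor (boundaries inclusive)."""
    if analysis_kind not in INCLUSION_N_FLOOR:
        raise ValueError(f"unknown analysis kind {analysis_kind!r}")
    floor = INCLUSION_N_FLOOR[analysis_kind]
    keep = (meta_records["k"] >= MIN_STUDIES) & (meta_records["n"] >= floor)
    logger.info("inclusion_filter(%s): %d of %d retained (k>=%d, n>=%d)",
                analysis_kind, int(keep.sum()), len(keep), MIN_STUDIES, floor)
    return meta_records.loc[keep].reset_index(drop=True)


def genomic_inflation(values, df: int = 1, kind: str = "chi2") -> float:
    """Genomic inflation factor: median observed chi-square over the
    reference chi-square median (0.4549 for 1 df, 2 ln 2 for 2 df).

    ``kind='log10p'`` converts log10 p-values to chi-square first.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("no test statistics supplied")
    if values.size < 100:
        logger.warning("genomic_inflation: only %d statistics; lambda is noisy", values.size)
    if kind == "log10p":
        values = _stats.log10p_to_chi2(values, df)
    elif kind != "chi2":
        raise ValueError("kind must be 'chi2' or 'log10p'")
    ref = _stats.CHI2_MEDIAN_1DF if df == 1 else _stats.CHI2_MEDIAN_2DF
    return float(np.median(values) / ref)
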