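"""Clumping + thresholding polygenic scores and the interaction-aware
combined score.

The pipeline follows the standard C+T recipe: residualize the phenotype on
age, age^2, sex and 10 PCs once on the full sample; split 2:1 into target
and validation sets; LD-clump the summary statistics (250 kb window,
r-squared 0.1, p 1.0); sweep p-value thresholds over [5e-8, 0.5] in 5e-5
steps; pick the threshold maximizing target-set R-squared; and freeze the
target-set mean and SD as standardization constants. Stratum-specific
scores (GG-only and GA-only summary statistics applied within the matching
stratum) are combined with the modifier genotype by the linear model

    y_res = w0 + w1*G + w2*(1-G)*PRS_GG + w3*G*PRS_GA + e,   G in {0, 1},

fitted on target-set GG/GA individuals.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _stats, ldhap
from .data import DEFAULT_COVARIATES, GenotypePanel, PhenotypeTable

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
GRID_LOWER = 5e-8
GRID_UPPER = 0.5
GRID_STEP = 5e-5


@dataclass
class PRSModel:
    source: str                     # 'unstratified' | 'GG' | 'GA'
    weights: pd.DataFrame           # variant_id, effect_allele, weight, eaf, log10_p
    p_threshold: float
    m: float                        # target-set raw-score mean
    s: float                        # target-set raw-score SD
    target_r2: float                # fraction (not percent)
    clump_params: tuple = (250.0, 0.1, 1.0)

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("standardization SD must be positive")


@dataclass
class CombinedScore:
    w: np.ndarray                   # (w0, w1, w2, w3)
    prs_gg: PRSModel
    prs_ga: PRSModel

    def predict(self, modifier, prs_gg_scores, prs_ga_scores):
        G = np.asarray(modifier, dtype=float)
        return (self.w[0] + self.w[1] * G
                + self.w[2] * (1 - G) * np.asarray(prs_gg_scores)
                + self.w[3] * G * np.asarray(prs_ga_scores))


def residualize_phenotype(pheno: PhenotypeTable, covariates=DEFAULT_COVARIATES,
                          column: str = "log_intake") -> np.ndarray:
    """OLS residuals of the phenotype on the covariates (mean exactly 0)."""
    y = pheno.data[column].to_numpy(dtype=float)
    C, names = pheno.covariate_matrix(covariates)
    _stats.check_full_rank(C, names)
    coef, _, _, _ = np.linalg.lstsq(C, y, rcond=None)
    resid = y - C @ coef
    return resid - resid.mean()  # exact zero mean despite round-off


def split_sample(n: int, seed: int):
    """Seeded random 2:1 target/validation partition: ceil(2n/3) target."""
    if n < 3:
        raise ValueError("need at least 3 individuals to split 2:1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_target = int(np.ceil(2 * n / 3))
    return np.sort(perm[:n_target]), np.sort(perm[n_target:])


def _harmonize(sumstats: pd.DataFrame, panel: GenotypePanel) -> pd.DataFrame:
    """Align summary statistics to the panel's ALT allele.

    Variants whose effect allele is the panel's REF get their beta negated
    and EAF complemented; A/T-G/C ambiguous variants are kept (matching by
    ID, not strand). Variants absent from the panel are dropped.
    """
    pv = panel.variants.set_index("id")
    ss = sumstats.loc[sumstats["variant_id"].isin(pv.index)].copy()
    dropped = len(sumstats) - len(ss)
    if dropped:
        logger.warning("harmonize: %d summary variants absent from panel, dropped", dropped)
    alt = ss["variant_id"].map(pv["alt"])
    ref = ss["variant_id"].map(pv["ref"])
    flipped = ss["effect_allele"].to_numpy() == ref.to_numpy()
    mismatch = (~flipped) & (ss["effect_allele"].to_numpy() != alt.to_numpy())
    if mismatch.any():
        raise ValueError("allele mismatch for variants: "
                         + ", ".join(ss.loc[mismatch, "variant_id"].head()))
    ss.loc[flipped, "beta"] = -ss.loc[flipped, "beta"]
    ss.loc[flipped, "eaf"] = 1.0 - ss.loc[flipped, "eaf"]
    ss.loc[flipped, "effect_allele"] = alt[flipped]
    return ss


def _raw_scores(panel: GenotypePanel, weights: pd.DataFrame,
                best_guess: bool = False) -> np.ndarray:
    """Sum_j beta_j G_ij over the weight table, mean-imputing missing
    variants as 2 x EAF from the model metadata."""
    score = np.zeros(panel.n_samples)
    present = set(panel.variant_ids)
    n_imputed = 0
    for _, row in weights.iterrows():
        if row["variant_id"] in present:
            g = panel.dosage(row["variant_id"])
            if best_guess:
                g = np.round(g)
        else:
            g = np.full(panel.n_samples, 2.0 * row["eaf"])
            n_imputed += 1
        score += row["weight"] * g
    if n_imputed:
        logger.info("score: %d variants mean-imputed as 2*EAF", n_imputed)
    return score


def simple_r2(predictor, outcome) -> float:
    """Simple-regression R-squared (= squared correlation with intercept)."""
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.std() == 0:
        raise ValueError("constant predictor")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def build_ct_prs(sumstats: pd.DataFrame, target_panel: GenotypePanel,
                 target_resid: np.ndarray, reference: GenotypePanel | None = None,
                 source: str = "unstratified", window_kb: float = 250.0,
                 r2_threshold: float = 0.1, clump_p: float = 1.0,
                 best_guess: bool = False) -> PRSModel:
    """Clumping + thresholding PRS construction.

    Summary p-values are floored at 1e-300; clumping uses ``reference``
    (the target panel by default); thresholds run from 5e-8 to 0.5 in 5e-5
    steps (endpoints inclusive); the selected model maximizes target-set
    R-squared of the raw score against the residual phenotype.
    """
    if reference is None:
        reference = target_panel
    ss = _harmonize(sumstats, target_panel).copy()
    ss["log10_p"] = np.maximum(ss["log10_p"], np.log10(P_FLOOR))
    if "pos" not in ss:
        ss = ss.merge(target_panel.variants[["id", "chrom", "pos"]],
                      left_on="variant_id", right_on="id", how="left").drop(columns="id")
    retained = ldhap.clump(ss, reference, window_kb=window_kb,
                           r2_threshold=r2_threshold, p_threshold=clump_p)
    ss = ss.loc[ss["variant_id"].isin(retained)].sort_values("log10_p").reset_index(drop=True)

    grid = np.arange(GRID_LOWER, GRID_UPPER + GRID_STEP / 2, GRID_STEP)
    log10_grid = np.log10(grid)
    # cumulative scores: variants sorted by ascending p, so each threshold
    # corresponds to a prefix of the weight list
    contrib = np.empty((len(ss), target_panel.n_samples))
    for i, row in ss.iterrows():
        g = target_panel.dosage(row["variant_id"])
        contrib[i] = row["weight" if "weight" in ss else "beta"] * (np.round(g) if best_guess else g)
    prefix_counts = np.searchsorted(ss["log10_p"].to_numpy(), log10_grid, side="right")
    # distinct prefixes only: every threshold mapping to the same variant
    # count yields the same score, so R2 is evaluated once per prefix and
    # the smallest qualifying grid threshold is reported
    best = None
    cum = np.zeros(target_panel.n_samples)
    done = 0
    for k in np.unique(prefix_counts):
        while done < k:
            cum += contrib[done]
            done += 1
        if k == 0 or cum.std() == 0:
            continue
        r2 = simple_r2(cum, target_resid)
        if best is None or r2 > best[0] + 1e-15:
            best = (r2, float(grid[np.argmax(prefix_counts == k)]), int(k), cum.copy())
    if best is None:
        raise ValueError("no variants at any grid threshold: empty score everywhere")
    r2, thr, k, raw = best
    weights = ss.iloc[:k][["variant_id", "effect_allele", "beta", "eaf", "log10_p"]].rename(
        columns={"beta": "weight"}).reset_index(drop=True)
    return PRSModel(source=source, weights=weights, p_threshold=float(thr),
                    m=float(raw.mean()), s=float(raw.std()), target_r2=float(r2),
                    clump_params=(window_kb, r2_threshold, clump_p))


def score(panel: GenotypePanel, model: PRSModel, best_guess: bool = False) -> np.ndarray:
    """Standardized PRS using the model's frozen target-set constants."""
    raw = _raw_scores(panel, model.weights, best_guess=best_guess)
    return (raw - model.m) / model.s


def fit_combined(modifier, prs_gg_scores, prs_ga_scores, resid) -> CombinedScore:
    """Fit the combined-score weights on target-set GG/GA individuals.

    ``modifier`` must already be coded GG = 0 / GA = 1 (AA excluded).
    """
    G = np.asarray(modifier, dtype=float)
    if set(np.unique(G)) - {0.0, 1.0}:
        raise ValueError("modifier must be coded 0 (GG) / 1 (GA); exclude AA first")
    if G.min() == G.max():
        raise ValueError("need both GG and GA individuals to fit the combined score")
    X = np.column_stack([np.ones_like(G), G,
                         (1 - G) * np.asarray(prs_gg_scores, dtype=float),
                         G * np.asarray(prs_ga_scores, dtype=float)])
    w, _, _, _ = np.linalg.lstsq(X, np.asarray(resid, dtype=float), rcond=None)
    return CombinedScore(w=w, prs_gg=None, prs_ga=None)


def evaluate_r2(predictor, resid) -> float:
    """Validation R-squared of a predictor against the residual phenotype,
    reported as a percentage."""
    return 100.0 * simple_r2(predictor, resid)
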