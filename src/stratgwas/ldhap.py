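"""Linkage disequilibrium, haplotype estimation, locus definition,
clumping, and approximate conditional analysis from summary statistics.

The haplotype machinery is built around the diagnostic configuration of a
modifier-tagging proxy variant: when one of the four two-locus haplotypes
is absent, D' = 1 while r-squared can be tiny, and a proxy allele that
rides exclusively on the modifier's wild-type haplotype flips the sign of
its association between unstratified and stratified scans.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _stats

logger = logging.getLogger(__name__)


@dataclass
class LDStats:
    variant_pair: tuple
    D: float
    Dprime: float
    r2: float
    p1: float         # ALT frequency, first variant
    p2: float         # ALT frequency, second variant
    source: str       # 'phased' or 'EM'


@dataclass
class HaplotypeTable:
    loci: list
    freqs: dict            # haplotype string -> frequency
    loglik: float
    iterations: int

    def __post_init__(self):
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")


def ld_from_hap_freqs(f11: float, p1: float, p2: float, pair=("v1", "v2"),
                      source: str = "phased") -> LDStats:
    """LD statistics from the ALT-ALT haplotype frequency and the two
    ALT-allele frequencies."""
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        raise ValueError("monomorphic variant: LD undefined")
    D = f11 - p1 * p2
    if D > 0:
        dmax = min(p1 * (1 - p2), (1 - p1) * p2)
    elif D < 0:
        dmax = min(p1 * p2, (1 - p1) * (1 - p2))
    else:
        dmax = np.nan
    dprime = 0.0 if D == 0 else abs(D) / dmax
    r2 = D**2 / (p1 * (1 - p1) * p2 * (1 - p2))
    return LDStats(tuple(pair), float(D), float(min(dprime, 1.0)), float(r2),
                   float(p1), float(p2), source)


def ld_pair(a1, a2, phased: bool = True, pair=("v1", "v2")) -> LDStats:
    """Pairwise LD between two biallelic variants.

    With ``phased=True``, ``a1``/``a2`` are haplotype allele arrays
    (anything broadcastable to per-haplotype 0/1, e.g. shape (n, 2)).
    With ``phased=False`` they are genotype dosage vectors (0/1/2) and the
    two-locus haplotype frequencies are resolved by EM.
    """
    a1 = np.asarray(a1)
    a2 = np.asarray(a2)
    if phased:
        h1 = a1.reshape(-1).astype(float)
        h2 = a2.reshape(-1).astype(float)
        p1, p2 = h1.mean(), h2.mean()
        f11 = np.mean(h1 * h2)
        return ld_from_hap_freqs(f11, p1, p2, pair, "phased")
    G = np.column_stack([a1, a2]).astype(float)
    if G[:, 0].std() == 0 or G[:, 1].std() == 0:
        raise ValueError("monomorphic variant: LD undefined")
    table = em_haplotypes(np.round(G).astype(int))
    f11 = table.freqs.get("1-1", 0.0)
    p1 = sum(f for h, f in table.freqs.items() if h.split("-")[0] == "1")
    p2 = sum(f for h, f in table.freqs.items() if h.split("-")[1] == "1")
    return ld_from_hap_freqs(f11, p1, p2, pair, "EM")


def _consistent_pairs(genotype):
    """All unordered haplotype pairs consistent with a multi-locus genotype.

    ``genotype`` is a tuple over loci with values 0/1/2. Returns a list of
    (hap_a, hap_b) tuples of 0/1 tuples.
    """
    het = [i for i, g in enumerate(genotype) if g == 1]
    base = [g // 2 if g != 1 else None for g in genotype]
    if not het:
        h = tuple(base)
        return [(h, h)]
    pairs = []
    # fix the first het locus to break the mirror symmetry
    for assign in itertools.product((0, 1), repeat=len(het) - 1):
        alleles = (0,) + assign
        ha, hb = list(base), list(base)
        for locus, al in zip(het, alleles):
            ha[locus] = al
            hb[locus] = 1 - al
        pairs.append((tuple(ha), tuple(hb)))
    return pairs


def em_haplotypes(G: np.ndarray, loci=None, allele_labels=None,
                  tol: float = 1e-8, max_iter: int = 1000) -> HaplotypeTable:
    """EM haplotype-frequency estimation from unphased genotypes.

    ``G`` is (n individuals x L loci) with ALT counts 0/1/2. L <= 20 (the
    diplotype expansion is exponential in the number of heterozygous
    loci). Initialization is uniform over the haplotypes consistent with
    the sample, so the run is deterministic. The log-likelihood is
    asserted non-decreasing at every step.

    ``allele_labels`` optionally gives (ref, alt) per locus to render
    haplotype strings like 'G-A'; the default renders ALT counts '0'/'1'.
    """
    G = np.asarray(G)
    n, L = G.shape
    if L > 20:
        raise ValueError("at most 20 loci supported (2^L haplotype enumeration)")
    for j in range(L):
        if np.all(np.isnan(G[:, j].astype(float))):
            raise ValueError(f"locus {j} is all-missing")
    patterns, counts = np.unique(G, axis=0, return_counts=True)
    pattern_pairs = [_consistent_pairs(tuple(p)) for p in patterns]
    hap_set = sorted({h for pairs in pattern_pairs for pair in pairs for h in pair})
    hap_index = {h: i for i, h in enumerate(hap_set)}
    H = len(hap_set)
    freqs = np.full(H, 1.0 / H)

    pair_idx = [np.array([(hap_index[a], hap_index[b]) for a, b in pairs])
                for pairs in pattern_pairs]
    loglik = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        new = np.zeros(H)
        ll = 0.0
        for cnt, idx in zip(counts, pair_idx):
            fa = freqs[idx[:, 0]]
            fb = freqs[idx[:, 1]]
            mult = np.where(idx[:, 0] == idx[:, 1], 1.0, 2.0)
            probs = mult * fa * fb
            tot = probs.sum()
            if tot <= 0:
                continue
            ll += cnt * np.log(tot)
            w = cnt * probs / tot
            np.add.at(new, idx[:, 0], w)
            np.add.at(new, idx[:, 1], w)
        assert ll >= loglik - 1e-9, "EM log-likelihood decreased"
        delta = np.max(np.abs(new / (2 * n) - freqs))
        freqs = new / (2 * n)
        loglik = ll
        if delta < tol:
            break

    def render(h):
        if allele_labels is None:
            return "-".join(str(a) for a in h)
        return "-".join(allele_labels[j][a] for j, a in enumerate(h))

    out = {render(h): float(freqs[hap_index[h]]) for h in hap_set}
    # normalize away accumulated round-off
    s = sum(out.values())
    out = {k: v / s for k, v in out.items()}
    if loci is None:
        loci = list(range(L))
    return HaplotypeTable(list(loci), out, float(loglik), it)


def explained_fraction(table: HaplotypeTable, subset) -> float:
    """Summed frequency of a subset of the table's haplotypes."""
    for h in subset:
        if h not in table.freqs:
            raise KeyError(f"unknown haplotype {h!r}")
    return float(sum(table.freqs[h] for h in subset))


def define_loci(meta_records: pd.DataFrame, log10_p_threshold: float = np.log10(5e-8),
                merge_distance: int = 1_000_000) -> pd.DataFrame:
    """Greedy locus definition: repeatedly take the most significant
    remaining genome-wide-significant SNP as a lead and absorb significant
    SNPs within the merge distance on the same chromosome. Ties broken by
    smaller position."""
    sig = meta_records.loc[meta_records["log10_p"] <= log10_p_threshold].copy()
    if len(sig) == 0:
        return pd.DataFrame(columns=["locus", "lead_variant", "chrom", "pos",
                                     "log10_p", "n_members", "members"])
    sig = sig.sort_values(["log10_p", "pos"], kind="mergesort").reset_index(drop=True)
    taken = np.zeros(len(sig), dtype=bool)
    loci = []
    for i in range(len(sig)):
        if taken[i]:
            continue
        lead = sig.iloc[i]
        same = (~taken) & (sig["chrom"] == lead["chrom"]).to_numpy() & \
            (np.abs(sig["pos"].to_numpy() - lead["pos"]) <= merge_distance)
        members = sig.loc[same, "variant_id"].tolist()
        taken |= same
        loci.append({"locus": len(loci) + 1, "lead_variant": lead["variant_id"],
                     "chrom": lead["chrom"], "pos": int(lead["pos"]),
                     "log10_p": float(lead["log10_p"]), "n_members": len(members),
                     "members": members})
    return pd.DataFrame(loci)


def clump(records: pd.DataFrame, reference, window_kb: float = 250.0,
          r2_threshold: float = 0.1, p_threshold: float = 1.0) -> list[str]:
    """LD clumping: iterate variants by ascending p; each retained index
    variant removes variants within +-window_kb with r-squared above the
    threshold. Index variants are retained regardless of window overlap.

    ``reference`` is a GenotypePanel supplying dosages for r-squared;
    variants absent from the reference are dropped with a warning.
    Distances are base-pair center-to-center, window inclusive.
    """
    ref_ids = {vid: j for j, vid in enumerate(reference.variant_ids)}
    rec = records.loc[records["log10_p"] <= np.log10(p_threshold) + 1e-12].copy()
    missing = [v for v in rec["variant_id"] if v not in ref_ids]
    if missing:
        logger.warning("clump: %d variants absent from reference, dropped", len(missing))
        rec = rec.loc[rec["variant_id"].isin(ref_ids)]
    rec = rec.sort_values(["log10_p", "pos"], kind="mergesort")
    window = window_kb * 1000.0
    D = reference.dosages
    sd = D.std(axis=0)
    retained: list[str] = []
    removed: set[str] = set()
    rows = rec[["variant_id", "chrom", "pos"]].to_records(index=False)
    for i, (vid, chrom, pos) in enumerate(rows):
        if vid in removed:
            continue
        retained.append(vid)
        gi = D[:, ref_ids[vid]]
        for vid2, chrom2, pos2 in rows[i + 1:]:
            if vid2 in removed or chrom2 != chrom or abs(pos2 - pos) > window:
                continue
            j = ref_ids[vid2]
            if sd[j] == 0 or sd[ref_ids[vid]] == 0:
                continue
            r = np.corrcoef(gi, D[:, j])[0, 1]
            if r * r > r2_threshold:
                removed.add(vid2)
    return retained


def conditional_joint(sumstats: pd.DataFrame, reference, lead_snps,
                      log10_p_threshold: float = np.log10(5e-8),
                      collinearity_r: float = 0.9) -> pd.DataFrame:
    """Approximate conditional analysis from summary statistics.

    For each candidate variant, the marginal effects of the conditioning
    set plus the candidate are mapped to the standardized-genotype scale
    (b_std = beta * sd(g) / sd(y)) and the joint estimates solve the
    LD-weighted normal equations b_joint = R^{-1} b_marginal, with
    covariance R^{-1}/n. Results are mapped back to the allele-count
    scale. sd(y) is profiled from the median of n * se^2 * var(g) across
    input variants (weak-effect approximation). Candidates correlated
    above ``collinearity_r`` with the conditioning set are skipped.
    """
    ss = sumstats.set_index("variant_id")
    lead_snps = [v for v in lead_snps]
    ids = list(ss.index)
    gsd = {}
    for vid in ids:
        g = reference.dosage(vid)
        gsd[vid] = g.std()
    var_y = float(np.median([ss.loc[v, "n"] * ss.loc[v, "se"] ** 2 * gsd[v] ** 2
                             for v in ids if gsd[v] > 0]))
    sy = np.sqrt(var_y)

    def corr(v1, v2):
        return float(np.corrcoef(reference.dosage(v1), reference.dosage(v2))[0, 1])

    rows = []
    for vid in ids:
        if vid in lead_snps or gsd[vid] == 0:
            continue
        cond = list(lead_snps)
        rs = [corr(vid, c) for c in cond]
        if any(abs(r) > collinearity_r for r in rs):
            logger.info("conditional_joint: %s collinear with conditioning set, skipped", vid)
            continue
        sel = cond + [vid]
        k = len(sel)
        R = np.eye(k)
        for a in range(k):
            for b in range(a + 1, k):
                R[a, b] = R[b, a] = corr(sel[a], sel[b])
        b_std = np.array([ss.loc[v, "beta"] * gsd[v] / sy for v in sel])
        n = float(np.min([ss.loc[v, "n"] for v in sel]))
        Rinv = np.linalg.inv(R)
        b_joint = Rinv @ b_std
        cov = Rinv / n
        beta_c = b_joint[-1] * sy / gsd[vid]
        se_c = np.sqrt(cov[-1, -1]) * sy / gsd[vid]
        lp = float(_stats.log10_sf_norm_twosided(b_joint[-1] / np.sqrt(cov[-1, -1])))
        rows.append({"variant_id": vid, "beta_cond": beta_c, "se_cond": se_c,
                     "log10_p_cond": lp,
                     "independent_signal": lp <= log10_p_threshold})
    return pd.DataFrame(rows)
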