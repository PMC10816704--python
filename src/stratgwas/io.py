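"""File formats: VCF 4.2 genotype panels, TSV phenotype tables, and the
METAL-like summary-statistics dialect.

Conventions: all genomic coordinates are 1-based inclusive; summary
statistics are tab-separated with p-values serialized as log10 (no
underflow); dosages round-trip at 1e-4 precision. Gzip is transparent on
read (by extension).
"""
from __future__ import annotations

import gzip
import logging

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .data import GenotypePanel, PhenotypeTable

logger = logging.getLogger(__name__)

SUMSTATS_REQUIRED = ("variant_id", "chrom", "pos", "effect_allele", "other_allele",
                     "eaf", "beta", "se", "log10_p", "n")
SUMSTATS_OPTIONAL = ("beta_int", "se_int", "cov_snp_int", "stratum", "model",
                     "study", "log10_p_int", "chi2_2df")


def write_vcf(path, panel: GenotypePanel, dosage_decimals: int = 4,
              modifier_id: str | None = None) -> None:
    """Write a panel as VCF 4.2 with GT (hard-call or phased) and DS fields."""
    phased = panel.phased
    sep = "|" if phased is not None else "/"
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(panel.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="ALT dosage">\n')
        fh.write('##INFO=<ID=RSQ,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, panel.samples)) + "\n")
        for j, v in panel.variants.iterrows():
            ds = panel.dosages[:, j]
            if phased is not None:
                gts = [f"{a}{sep}{b}" for a, b in phased[:, :, j]]
            else:
                hard = np.round(ds).astype(int)
                gts = ["0/0" if h == 0 else ("0/1" if h == 1 else "1/1") for h in hard]
            fields = [f"{g}:{d:.{dosage_decimals}f}" for g, d in zip(gts, ds)]
            fh.write(f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t{v['alt']}"
                     f"\t.\tPASS\tRSQ={v['qual']:g}\tGT:DS\t" + "\t".join(fields) + "\n")


def read_vcf(path, modifier_id: str, mode: str = "auto") -> GenotypePanel:
    """Read a VCF into a GenotypePanel.

    ``mode``: 'auto' prefers DS when present, 'dosage' requires DS,
    'hardcall' requires GT. The modifier genotype is taken from the
    hard calls of ``modifier_id`` (never from dosage). Multiallelic
    records are skipped with a warning.
    """
    vcf = VCF(str(path))
    samples = np.array(vcf.samples)
    ids, chroms, poss, refs, alts, quals = [], [], [], [], [], []
    dosage_cols = []
    phased_cols = []
    all_phased = True
    modifier = None
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gt = np.array(var.genotypes)  # (n, 3): allele1, allele2, phased flag
        if gt.shape[1] < 3:
            raise ValueError("mixed or unexpected ploidy in VCF")
        ds = None
        if mode in ("auto", "dosage"):
            try:
                ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
            except (TypeError, KeyError):
                ds = None
        if ds is None:
            if mode == "dosage":
                raise ValueError("VCF record lacks DS in dosage mode")
            if np.any(gt[:, 0] < 0):
                raise ValueError("missing GT hard calls")
            ds = (gt[:, 0] + gt[:, 1]).astype(float)
        elif mode == "hardcall":
            ds = (gt[:, 0] + gt[:, 1]).astype(float)
        if np.any(gt[:, 0] < 0) and mode == "hardcall":
            raise ValueError("hard-call mode requires GT for every sample")
        dosage_cols.append(ds)
        if not np.all(gt[:, 2]):
            all_phased = False
        phased_cols.append(gt[:, :2].astype(np.int8))
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        ids.append(vid)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rsq = var.INFO.get("RSQ")
        quals.append(float(rsq) if rsq is not None else 1.0)
        if vid == modifier_id:
            modifier = (gt[:, 0] + gt[:, 1]).astype(int)
    if n_multi:
        logger.warning("read_vcf: skipped %d multiallelic records", n_multi)
    if modifier is None:
        raise ValueError(f"modifier variant {modifier_id!r} not found in VCF")
    dosages = np.column_stack(dosage_cols)
    variants = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss,
                             "ref": refs, "alt": alts, "qual": quals,
                             "eaf": dosages.mean(axis=0) / 2.0})
    phased = np.stack(phased_cols, axis=2) if all_phased else None
    return GenotypePanel(samples=samples, variants=variants, dosages=dosages,
                         modifier=modifier, phased=phased)


def write_phenotypes(path, pheno: PhenotypeTable) -> None:
    pheno.data.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(data=pd.read_csv(path, sep="\t"))


def write_sumstats(path, records: pd.DataFrame) -> None:
    """Write association/meta records as METAL-like TSV (log10 p on disk)."""
    for c in SUMSTATS_REQUIRED:
        if c not in records and c not in ("chrom", "pos"):
            raise ValueError(f"missing mandatory column {c!r}")
    records.to_csv(path, sep="\t", index=False)


def read_sumstats(path, required=None) -> pd.DataFrame:
    """Read METAL-like TSV; column order is free, mandatory columns and
    numeric cells validated with row-level error reporting."""
    df = pd.read_csv(path, sep="\t")
    req = [c for c in (required or SUMSTATS_REQUIRED) if c not in ("chrom", "pos")]
    for c in req:
        if c not in df.columns:
            raise ValueError(f"missing mandatory column {c!r}")
    for c in ("eaf", "beta", "se", "log10_p", "n"):
        if c in df.columns:
            coerced = pd.to_numeric(df[c], errors="coerce")
            bad = coerced.isna() & df[c].notna()
            if bad.any():
                raise ValueError(f"non-numeric value in column {c!r} at rows "
                                 f"{list(df.index[bad][:5])}")
            df[c] = coerced
    return df


def write_sim_config(path, config) -> None:
    """Serialize a SimConfig next to generated outputs for provenance."""
    from .synthdata import SimConfig  # noqa: F401 (documented type)
    d = {
        "seed": int(config.seed),
        "cohort_sizes": [int(x) for x in config.cohort_sizes],
        "hap_freqs": {k: float(v) for k, v in config.hap_freqs.items()},
        "n_background_snps": int(config.n_background_snps),
        "maf_range": [float(x) for x in config.maf_range],
        "ld_block_spec": [[int(a), float(b)] for a, b in config.ld_block_spec],
        "tau2": float(config.tau2),
        "case_control_ratio": config.case_control_ratio,
        "effects": {
            "beta0": float(config.effects.beta0),
            "beta_mod": float(config.effects.beta_mod),
            "beta_snp": {k: float(v) for k, v in config.effects.beta_snp.items()},
            "beta_int": {k: float(v) for k, v in config.effects.beta_int.items()},
            "gamma_cov": {k: float(v) for k, v in config.effects.gamma_cov.items()},
            "sigma": float(config.effects.sigma),
            "disease_alpha": config.effects.disease_alpha,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_sim_config(path):
    from .synthdata import EffectSpec, SimConfig
    with open(path) as fh:
        d = yaml.safe_load(fh)
    eff = d.pop("effects", {})
    return SimConfig(
        effects=EffectSpec(**eff),
        cohort_sizes=tuple(d.pop("cohort_sizes")),
        maf_range=tuple(d.pop("maf_range")),
        ld_block_spec=tuple((int(a), float(b)) for a, b in d.pop("ld_block_spec", [])),
        **d,
    )
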