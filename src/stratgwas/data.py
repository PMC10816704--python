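"""Core in-memory containers: genotype panels and phenotype tables.

A :class:`GenotypePanel` holds per-individual ALT-allele dosages in [0, 2]
for an ordered set of biallelic variants, plus the directly genotyped
effect-modifier genotype (0 = GG wild-type homozygote, 1 = GA heterozygote,
2 = AA variant homozygote). Optionally the phased haplotypes are kept
(shape n x 2 x m, alleles coded 0/1).

A :class:`PhenotypeTable` wraps a per-individual pandas DataFrame with the
alcohol phenotypes (raw grams/day, its log2(g/day + 1) transform, ever/never
drinking status), case status for the disease analyses, and the covariates
(age, sex, 10 principal components). Age squared is always derived from age
when building design matrices, never stored.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: covariate set used by the association scans: age, age^2 (derived), sex, 10 PCs
DEFAULT_COVARIATES = ("age", "age2", "sex") + tuple(f"PC{i}" for i in range(1, 11))

PHENO_COLUMNS = ("intake_gday", "log_intake", "drinking_status", "case_status")


@dataclass
class GenotypePanel:
    samples: np.ndarray                 # (n,) sample IDs
    variants: pd.DataFrame              # columns: id, chrom, pos, ref, alt, qual, eaf
    dosages: np.ndarray                 # (n, m) float in [0, 2], ALT allele count
    modifier: np.ndarray                # (n,) int in {0, 1, 2}; never missing
    phased: np.ndarray | None = None    # (n, 2, m) int8 alleles, optional

    def __post_init__(self):
        self.samples = np.asarray(self.samples)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.modifier = np.asarray(self.modifier, dtype=int)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x variants)")
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage matrix shape does not match samples/variants")
        if self.dosages.size and (self.dosages.min() < -1e-9 or self.dosages.max() > 2 + 1e-9):
            raise ValueError("dosages must lie in [0, 2]")
        if np.any((self.modifier < 0) | (self.modifier > 2)):
            raise ValueError("modifier genotype must be 0 (GG), 1 (GA) or 2 (AA)")
        self.variants = self.variants.reset_index(drop=True)
        # positions strictly increasing within chromosome
        for _, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("variant positions must be strictly increasing within a chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["id"].to_numpy()

    def index_of(self, variant_id: str) -> int:
        # panels are treated as immutable after construction; cache the map
        idx = self.__dict__.get("_id_index")
        if idx is None or len(idx) != len(self.variants):
            idx = {v: j for j, v in enumerate(self.variants["id"])}
            self.__dict__["_id_index"] = idx
        if variant_id not in idx:
            raise KeyError(f"unknown variant ID: {variant_id!r}")
        return idx[variant_id]

    def dosage(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.index_of(variant_id)]

    def eaf(self) -> np.ndarray:
        """Empirical ALT-allele frequency per variant."""
        return self.dosages.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.eaf()
        return np.minimum(f, 1.0 - f)

    def subset_samples(self, mask: np.ndarray) -> "GenotypePanel":
        mask = np.asarray(mask)
        return GenotypePanel(
            samples=self.samples[mask],
            variants=self.variants.copy(),
            dosages=self.dosages[mask],
            modifier=self.modifier[mask],
            phased=None if self.phased is None else self.phased[mask],
        )

    def subset_variants(self, keep: np.ndarray) -> "GenotypePanel":
        """Keep variants by boolean mask or integer index (order preserved)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypePanel(
            samples=self.samples,
            variants=self.variants.iloc[keep].reset_index(drop=True),
            dosages=self.dosages[:, keep],
            modifier=self.modifier,
            phased=None if self.phased is None else self.phased[:, :, keep],
        )


@dataclass
class PhenotypeTable:
    data: pd.DataFrame
    #: for case-control designs: fraction of simulated controls retained
    sampling_fraction: float | None = None

    def __post_init__(self):
        self.data = self.data.reset_index(drop=True)
        if "intake_gday" in self.data and "log_intake" in self.data:
            raw = self.data["intake_gday"].to_numpy(dtype=float)
            lg = self.data["log_intake"].to_numpy(dtype=float)
            ok = ~np.isnan(raw)
            if not np.allclose(lg[ok], np.log2(raw[ok] + 1.0), atol=1e-8):
                raise ValueError("log_intake must equal log2(intake_gday + 1)")
        for col in ("drinking_status", "case_status"):
            if col in self.data:
                vals = self.data[col].dropna().unique()
                if not set(np.asarray(vals)).issubset({0, 1}):
                    raise ValueError(f"{col} must be binary 0/1")

    def __len__(self) -> int:
        return len(self.data)

    def covariate_matrix(self, covariates=DEFAULT_COVARIATES) -> tuple[np.ndarray, list[str]]:
        """Design block [intercept, covariates...]; 'age2' is derived from age."""
        cols = [np.ones(len(self.data))]
        names = ["intercept"]
        for c in covariates:
            if c == "age2":
                cols.append(self.data["age"].to_numpy(dtype=float) ** 2)
            else:
                cols.append(self.data[c].to_numpy(dtype=float))
            names.append(c)
        return np.column_stack(cols), names

    def subset(self, mask: np.ndarray) -> "PhenotypeTable":
        return replace(self, data=self.data.loc[np.asarray(mask)].reset_index(drop=True))


def stratum_mask(panel: GenotypePanel, stratum: str) -> np.ndarray:
    """Individuals in a modifier-genotype stratum.

    ``all`` keeps everyone; ``GG`` and ``GA`` select by the direct modifier
    genotype. AA-homozygote-only analysis is deliberately not offered (too
    few ever-drinkers to support it), so ``AA`` is rejected.
    """
    if stratum == "all":
        return np.ones(panel.n_samples, dtype=bool)
    if stratum == "GG":
        return panel.modifier == 0
    if stratum == "GA":
        return panel.modifier == 1
    raise ValueError(f"unknown stratum {stratum!r}; use 'all', 'GG' or 'GA'")
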