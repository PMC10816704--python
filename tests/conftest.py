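import numpy as np
import pandas as pd
import pytest

import stratgwas as sg


@pytest.fixture(scope="session")
def default_panel():
    """One moderately sized cohort with the three-haplotype modifier region."""
    cfg = sg.SimConfig(seed=101, cohort_sizes=(6000,), n_background_snps=40)
    return sg.simulate_panel(cfg)


@pytest.fixture(scope="session")
def default_pheno(default_panel):
    spec = sg.EffectSpec(beta0=3.0, beta_mod=-1.8, sigma=2.0)
    return sg.simulate_quantitative(default_panel, spec, seed=102)


def make_panel(dosages, modifier=None, chrom="1", pos0=1_000_000, spacing=500_000,
               phased=None):
    """Small helper: wrap a dosage matrix as a GenotypePanel."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame({
        "id": [f"v{j}" for j in range(m)],
        "chrom": chrom,
        "pos": [pos0 + spacing * j for j in range(m)],
        "ref": "G", "alt": "A", "qual": 1.0,
        "eaf": dosages.mean(axis=0) / 2.0,
    })
    if modifier is None:
        modifier = np.zeros(n, dtype=int)
    return sg.GenotypePanel(samples=np.array([f"s{i}" for i in range(n)]),
                            variants=variants, dosages=dosages,
                            modifier=modifier, phased=phased)


def make_pheno(n, rng=None, **columns):
    """Phenotype table with standard covariates plus supplied outcome columns."""
    rng = rng or np.random.default_rng(0)
    data = {"age": rng.normal(55, 10, n), "sex": rng.integers(0, 2, n).astype(float)}
    for i in range(1, 11):
        data[f"PC{i}"] = rng.standard_normal(n)
    data.update(columns)
    return sg.PhenotypeTable(data=pd.DataFrame(data))
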