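"""LD statistics, EM haplotype estimation, locus definition, clumping and
approximate conditional analysis."""
import numpy as np
import pandas as pd
import pytest

import stratgwas as sg
from stratgwas import _stats, ldhap
from conftest import make_panel


class TestLDPair:
    def test_three_haplotype_closed_form(self):
        ld = ldhap.ld_from_hap_freqs(0.0, 0.25, 0.17)
        assert ld.Dprime == pytest.approx(1.0)
        assert ld.r2 == pytest.approx(0.0683, abs=5e-4)

    def test_self_ld(self):
        rng = np.random.default_rng(30)
        h = rng.binomial(1, 0.3, (500, 2))
        ld = ldhap.ld_pair(h, h)
        assert ld.Dprime == pytest.approx(1.0)
        assert ld.r2 == pytest.approx(1.0)

    def test_independent_variants_near_zero(self):
        rng = np.random.default_rng(31)
        h1 = rng.binomial(1, 0.3, (100_000, 2))
        h2 = rng.binomial(1, 0.4, (100_000, 2))
        assert ldhap.ld_pair(h1, h2).r2 < 0.001

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            ldhap.ld_pair(np.zeros((50, 2)), np.ones((50, 2)))

    def test_phased_and_em_agree(self):
        cfg = sg.SimConfig(seed=32, cohort_sizes=(10_000,), n_background_snps=2)
        panel = sg.simulate_panel(cfg)
        phased = ldhap.ld_pair(panel.phased[:, :, 0], panel.phased[:, :, 1])
        unphased = ldhap.ld_pair(panel.dosages[:, 0], panel.dosages[:, 1], phased=False)
        assert unphased.source == "EM"
        assert unphased.r2 == pytest.approx(phased.r2, abs=1e-3)
        assert unphased.Dprime == pytest.approx(phased.Dprime, abs=1e-3)


class TestEMHaplotypes:
    def test_unambiguous_gamete_counts(self):
        # no double heterozygote: frequencies are direct gamete counts
        G = np.array([[0, 0], [2, 2], [2, 0], [1, 0], [0, 2]])
        t = ldhap.em_haplotypes(G)
        counts = {"0-0": 3, "1-1": 2, "1-0": 3, "0-1": 2}
        for h, c in counts.items():
            assert t.freqs.get(h, 0.0) == pytest.approx(c / 10, abs=1e-9)

    def test_single_double_heterozygote_symmetric(self):
        t = ldhap.em_haplotypes(np.array([[1, 1]]))
        assert all(f == pytest.approx(0.25) for f in t.freqs.values())

    def test_three_haplotype_recovery(self):
        cfg = sg.SimConfig(seed=33, cohort_sizes=(10_000,), n_background_snps=2)
        panel = sg.simulate_panel(cfg)
        G = np.round(panel.dosages[:, :2]).astype(int)
        t = ldhap.em_haplotypes(G, allele_labels=[("G", "A"), ("G", "A")])
        assert t.freqs.get("A-A", 0.0) < 0.005
        for h, f in sg.DEFAULT_HAP_FREQS.items():
            assert t.freqs[h] == pytest.approx(f, abs=0.01)

    def test_loglik_monotone_and_l_cap(self):
        with pytest.raises(ValueError, match="20 loci"):
            ldhap.em_haplotypes(np.zeros((5, 21), dtype=int))


class TestExplainedFraction:
    def test_completeness(self):
        t = ldhap.HaplotypeTable([0, 1], {"0-0": 0.6, "1-0": 0.4}, 0.0, 1)
        assert ldhap.explained_fraction(t, ["0-0", "1-0"]) == pytest.approx(1.0)

    def test_default_panel_three_haplotypes(self, default_panel):
        G = np.round(default_panel.dosages[:, :2]).astype(int)
        t = ldhap.em_haplotypes(G, allele_labels=[("G", "A"), ("G", "A")])
        subset = [h for h in ("G-G", "A-G", "G-A") if h in t.freqs]
        assert ldhap.explained_fraction(t, subset) == pytest.approx(1.0, abs=1e-6)

    def test_perturbed_panel_stays_high(self, default_panel):
        rng = np.random.default_rng(34)
        G = np.round(default_panel.dosages[:, :2]).astype(int)
        err = rng.random(G.shape) < 0.01
        G = np.clip(G + err * rng.choice([-1, 1], G.shape), 0, 2)
        t = ldhap.em_haplotypes(G, allele_labels=[("G", "A"), ("G", "A")])
        subset = [h for h in ("G-G", "A-G", "G-A") if h in t.freqs]
        assert ldhap.explained_fraction(t, subset) >= 0.98

    def test_unknown_haplotype_rejected(self):
        t = ldhap.HaplotypeTable([0], {"0": 1.0}, 0.0, 1)
        with pytest.raises(KeyError):
            ldhap.explained_fraction(t, ["1"])


def meta_like(ids, chroms, poss, log10_ps):
    return pd.DataFrame({"variant_id": ids, "chrom": chroms, "pos": poss,
                         "log10_p": log10_ps})


class TestDefineLoci:
    def test_merge_within_distance(self):
        rec = meta_like(["a", "b"], ["1", "1"], [1_000_000, 1_500_000], [-10, -9])
        loci = ldhap.define_loci(rec)
        assert len(loci) == 1 and loci["lead_variant"].iloc[0] == "a"

    def test_split_beyond_distance(self):
        rec = meta_like(["a", "b"], ["1", "1"], [1_000_000, 2_500_000], [-10, -9])
        assert len(ldhap.define_loci(rec)) == 2

    def test_planted_regions_recovered(self):
        rng = np.random.default_rng(35)
        pos = np.arange(200) * 100_000 + 1
        lp = -rng.uniform(0, 3, 200)
        leads = {}
        for center, depth in ((30, -40.0), (90, -25.0), (160, -12.0)):
            for off in (-2, -1, 0, 1, 2):
                lp[center + off] = depth + abs(off) * 3 + rng.uniform(0, 0.5)
            leads[f"v{center}"] = center
        rec = meta_like([f"v{i}" for i in range(200)], "1", pos, lp)
        loci = ldhap.define_loci(rec)
        assert len(loci) == 3
        assert set(loci["lead_variant"]) == set(leads)

    def test_empty_when_no_hits(self):
        rec = meta_like(["a"], ["1"], [100], [-3.0])
        assert len(ldhap.define_loci(rec)) == 0


def brute_force_clump(rec, r2_matrix, window):
    """Independent reference: greedy over a precomputed r2 matrix."""
    order = rec.sort_values(["log10_p", "pos"], kind="mergesort").index.tolist()
    removed, kept = set(), []
    for i in order:
        if i in removed:
            continue
        kept.append(rec.loc[i, "variant_id"])
        for j in order:
            if j == i or j in removed:
                continue
            same = rec.loc[j, "chrom"] == rec.loc[i, "chrom"]
            close = abs(rec.loc[j, "pos"] - rec.loc[i, "pos"]) <= window
            if same and close and r2_matrix[i, j] > 0.1:
                removed.add(j)
    return kept


class TestClump:
    def test_textbook_example(self):
        # A(p=1e-10), B(p=1e-5, r2=0.5 with A, 50 kb), C(p=1e-6, r2=0.05)
        rng = np.random.default_rng(36)
        n = 4000
        a = rng.binomial(2, 0.3, n).astype(float)
        noise = rng.binomial(2, 0.3, n).astype(float)
        b = np.where(rng.random(n) < 0.72, a, noise)  # strongly correlated
        c = rng.binomial(2, 0.3, n).astype(float)     # independent
        panel = make_panel(np.column_stack([a, b, c]), spacing=50_000)
        r2ab = np.corrcoef(a, b)[0, 1] ** 2
        assert r2ab > 0.3
        rec = pd.DataFrame({"variant_id": ["v0", "v1", "v2"], "chrom": "1",
                            "pos": panel.variants["pos"], "log10_p": [-10, -5, -6]})
        assert ldhap.clump(rec, panel) == ["v0", "v2"]

    def test_independent_all_retained(self):
        rng = np.random.default_rng(37)
        panel = make_panel(rng.binomial(2, 0.3, (3000, 6)).astype(float), spacing=10_000)
        rec = pd.DataFrame({"variant_id": [f"v{j}" for j in range(6)], "chrom": "1",
                            "pos": panel.variants["pos"],
                            "log10_p": -rng.uniform(1, 9, 6)})
        assert sorted(ldhap.clump(rec, panel)) == [f"v{j}" for j in range(6)]

    def test_oracle_equivalence_on_ld_blocks(self):
        cfg = sg.SimConfig(seed=38, cohort_sizes=(3000,), n_background_snps=30,
                           ld_block_spec=((10, 0.9), (10, 0.7)), maf_range=(0.2, 0.5))
        panel = sg.simulate_panel(cfg).subset_variants(np.arange(2, 32))
        # compress positions so windows overlap within blocks
        panel.variants["pos"] = 1_000_000 + 40_000 * np.arange(30)
        rng = np.random.default_rng(39)
        rec = pd.DataFrame({"variant_id": panel.variant_ids, "chrom": "1",
                            "pos": panel.variants["pos"],
                            "log10_p": -rng.uniform(0.1, 12, 30)})
        r2m = np.corrcoef(panel.dosages.T) ** 2
        expect = brute_force_clump(rec.reset_index(drop=True), r2m, 250_000)
        assert ldhap.clump(rec, panel) == expect


class TestConditionalJoint:
    @staticmethod
    def _sumstats(y, G, panel):
        b, se, lp, _ = _stats.ols_scan(y, G, np.ones((len(y), 1)))
        return pd.DataFrame({"variant_id": panel.variant_ids, "beta": b, "se": se,
                             "log10_p": lp, "n": len(y),
                             "eaf": panel.eaf()})

    def test_orthogonal_equals_marginal(self):
        rng = np.random.default_rng(40)
        n = 5000
        G = rng.binomial(2, [0.3, 0.4], (n, 2)).astype(float)
        y = 0.2 * G[:, 0] + 0.15 * G[:, 1] + rng.normal(0, 1, n)
        panel = make_panel(G)
        ss = self._sumstats(y, G, panel)
        res = ldhap.conditional_joint(ss, panel, ["v0"]).iloc[0]
        # r ~ 0: conditional estimate approximately the marginal one
        assert res["beta_cond"] == pytest.approx(ss["beta"].iloc[1], abs=0.02)

    def test_perfect_collinearity_skipped(self):
        rng = np.random.default_rng(41)
        n = 1000
        g = rng.binomial(2, 0.3, n).astype(float)
        G = np.column_stack([g, g])
        y = g * 0.3 + rng.normal(0, 1, n)
        panel = make_panel(G)
        ss = self._sumstats(y, G, panel)
        res = ldhap.conditional_joint(ss, panel, ["v0"])
        assert len(res) == 0  # candidate dropped as collinear

    def test_matches_individual_level_joint_fit(self):
        rng = np.random.default_rng(42)
        n = 2000
        hits = 0
        reps = 100
        for _ in range(reps):
            g1 = rng.binomial(2, 0.3, n).astype(float)
            mix = rng.random(n) < 0.45
            g2 = np.where(mix, g1, rng.binomial(2, 0.3, n)).astype(float)
            y = 0.15 * g1 + 0.1 * g2 + rng.normal(0, 1, n)
            panel = make_panel(np.column_stack([g1, g2]))
            ss = self._sumstats(y, np.column_stack([g1, g2]), panel)
            res = ldhap.conditional_joint(ss, panel, ["v0"]).iloc[0]
            X = np.column_stack([np.ones(n), g1, g2])
            coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            hits += abs(res["beta_cond"] - coef[2]) < 2 * res["se_cond"]
        assert hits / reps >= 0.95
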