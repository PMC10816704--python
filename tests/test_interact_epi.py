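"""Case-control interaction: per-study fits, multivariate pooling, RERI,
multiplicative interaction, stratified OR pooling, control subsampling."""
import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import expit

import stratgwas as sg
from stratgwas import interact_epi
from conftest import make_panel, make_pheno


def case_control_sim(rng, n, b_snp, b_mod, b_int, intercept=-2.0, f=0.3, f_mod=0.25):
    g = rng.binomial(2, f, n).astype(float)
    mod = rng.binomial(1, f_mod, n)
    p = expit(intercept + b_snp * g + b_mod * mod + b_int * g * mod)
    y = rng.binomial(1, p)
    panel = make_panel(g[:, None], modifier=mod)
    pheno = make_pheno(n, rng, case_status=y)
    return panel, pheno


class TestStudyFit:
    def test_interaction_coefficient_recovery(self):
        hits = 0
        reps = 100
        for r in range(reps):
            rng = np.random.default_rng(500 + r)
            panel, pheno = case_control_sim(rng, 8000, 0.2, 0.4, np.log(1.5))
            fit = interact_epi.fit_study_interaction(panel, pheno, "v0",
                                                     covariates=("age", "sex"))
            se = np.sqrt(fit.cov[2, 2])
            hits += abs(fit.beta[2] - np.log(1.5)) < 1.96 * se
        assert hits / reps >= 0.90

    def test_separation_firth_fallback_finite(self):
        rng = np.random.default_rng(43)
        n = 400
        g = rng.binomial(2, 0.3, n).astype(float)
        mod = rng.binomial(1, 0.4, n)
        y = (g > 0).astype(int)  # cases iff SNP carrier: complete separation
        panel = make_panel(g[:, None], modifier=mod)
        pheno = make_pheno(n, rng, case_status=y)
        fit = interact_epi.fit_study_interaction(panel, pheno, "v0", covariates=())
        assert "Firth" in fit.flag
        assert np.all(np.isfinite(fit.beta))

    def test_constant_covariate_named(self):
        rng = np.random.default_rng(44)
        panel, pheno = case_control_sim(rng, 500, 0.0, 0.0, 0.0)
        pheno.data["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            interact_epi.fit_study_interaction(panel, pheno, "v0",
                                               covariates=("age", "flat"))

    def test_hardcall_coding(self):
        rng = np.random.default_rng(45)
        panel, pheno = case_control_sim(rng, 2000, 0.3, 0.2, 0.0)
        panel.dosages = np.clip(panel.dosages + rng.normal(0, 0.01, panel.dosages.shape), 0, 2)
        fit_d = interact_epi.fit_study_interaction(panel, pheno, "v0", covariates=())
        fit_h = interact_epi.fit_study_interaction(panel, pheno, "v0", covariates=(),
                                                   coding="hardcall")
        assert fit_d.beta[0] == pytest.approx(fit_h.beta[0], abs=0.05)


class TestMvMetaML:
    def test_identical_studies_passthrough(self):
        f = interact_epi.StudyFit(np.array([0.1, 0.2, 0.3]), 0.01 * np.eye(3), 100)
        b, S, Psi = interact_epi.mv_meta_ml([f, f, f])
        assert b == pytest.approx([0.1, 0.2, 0.3], abs=1e-6)
        assert np.abs(Psi).max() < 1e-4

    def test_single_study_identity(self):
        f = interact_epi.StudyFit(np.array([0.1, 0.2, 0.3]), 0.01 * np.eye(3), 100)
        b, S, Psi = interact_epi.mv_meta_ml([f])
        assert np.array_equal(b, f.beta)
        assert np.array_equal(S, f.cov)
        assert np.all(Psi == 0)

    def test_scalar_case_matches_univariate_ml_oracle(self):
        """In dimension 1 the pooled value matches a direct univariate
        random-effects ML optimization."""
        betas = np.array([0.1, 0.5, 0.3, 0.25])
        ses = np.array([0.1, 0.15, 0.08, 0.2])
        fits = [interact_epi.StudyFit(np.array([b]), np.array([[s**2]]), 100)
                for b, s in zip(betas, ses)]
        b, S, Psi = interact_epi.mv_meta_ml(fits)

        def nll(params):
            mu, log_tau2 = params
            v = ses**2 + np.exp(log_tau2)
            return 0.5 * np.sum(np.log(v) + (betas - mu) ** 2 / v)

        best = min(
            (optimize.minimize(nll, [m0, t0], method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-12})
             for m0 in (0.0, 0.3) for t0 in (-8, -3, -1)),
            key=lambda r: r.fun)
        mu_hat, tau2_hat = best.x[0], np.exp(best.x[1])
        assert b[0] == pytest.approx(mu_hat, abs=1e-4)
        assert Psi[0, 0] == pytest.approx(tau2_hat, abs=1e-3)

    def test_known_heterogeneity_recovery(self):
        """Random-effects pooling covers the true vector far better than
        fixed effects under real between-study heterogeneity; the plug-in
        Wald ellipse at k=6 studies undercovers slightly (a known
        small-sample property), so the nominal-rate check is one-sided."""
        rng = np.random.default_rng(46)
        true_b = np.array([0.2, 0.3, -0.1])
        Psi_true = np.diag([0.04, 0.02, 0.03])
        cover = cover_fe = 0
        psi_hats = []
        reps = 100
        for _ in range(reps):
            fits = []
            for _ in range(6):
                V = np.diag(rng.uniform(0.005, 0.02, 3))
                bi = rng.multivariate_normal(true_b, V + Psi_true)
                fits.append(interact_epi.StudyFit(bi, V, 100))
            b, S, Psi = interact_epi.mv_meta_ml(fits, method="reml")
            psi_hats.append(np.diag(Psi))
            d = b - true_b
            cover += d @ np.linalg.solve(S, d) < 7.8147  # chi2_3 95% quantile
            prec = sum(np.linalg.inv(f.cov) for f in fits)
            S_fe = np.linalg.inv(prec)
            b_fe = S_fe @ sum(np.linalg.inv(f.cov) @ f.beta for f in fits)
            d = b_fe - true_b
            cover_fe += d @ np.linalg.solve(S_fe, d) < 7.8147
        assert cover / reps >= 0.80
        assert cover > cover_fe
        # REML Psi-hat is close to unbiased for the diagonal
        assert np.mean(psi_hats, axis=0) == pytest.approx(np.diag(Psi_true), abs=0.02)


class TestRERI:
    def test_hand_computed_example(self):
        res = interact_epi.reri(np.array([np.log(2), np.log(2), 0.0]), 0.01 * np.eye(3))
        assert res.reri == pytest.approx(1.0)
        assert res.se == pytest.approx(np.sqrt(0.24), rel=1e-9)
        assert res.ci[0] == pytest.approx(0.04, abs=0.002)
        assert res.ci[1] == pytest.approx(1.96, abs=0.002)
        assert res.suggestive

    def test_null(self):
        res = interact_epi.reri(np.zeros(3), 0.01 * np.eye(3))
        assert res.reri == 0.0
        assert not res.suggestive

    def test_decomposition_identity(self):
        rng = np.random.default_rng(47)
        for _ in range(20):
            b = rng.normal(0, 0.7, 3)
            res = interact_epi.reri(b, 0.01 * np.eye(3))
            d = res.decomposition
            total = d["excess_snp"] + d["excess_mod"] + d["reri"] + d["baseline"]
            assert total == pytest.approx(res.joint_or, rel=1e-12)
            assert res.reri == pytest.approx(
                res.joint_or - res.or_snp - res.or_mod + 1.0, rel=1e-12)

    def test_delta_ci_close_to_parametric_bootstrap(self):
        rng = np.random.default_rng(48)
        b = np.array([np.log(2), np.log(2), 0.0])
        Sigma = 0.01 * np.eye(3)
        res = interact_epi.reri(b, Sigma)
        draws = rng.multivariate_normal(b, Sigma, 100_000)
        s = draws.sum(axis=1)
        reri_draws = np.exp(s) - np.exp(draws[:, 0]) - np.exp(draws[:, 1]) + 1
        lo, hi = np.percentile(reri_draws, [2.5, 97.5])
        assert (res.ci[1] - res.ci[0]) == pytest.approx(hi - lo, rel=0.05)

    def test_multiplicative_examples(self):
        or_int, ci, lp = interact_epi.multiplicative_interaction(
            np.array([0.0, 0.0, 0.0]), np.diag([1, 1, 0.01]))
        assert or_int == pytest.approx(1.0)
        assert ci[0] == pytest.approx(0.822, abs=0.005)
        assert ci[1] == pytest.approx(1.217, abs=0.005)
        or2, _, _ = interact_epi.multiplicative_interaction(
            np.array([0, 0, np.log(2)]), np.eye(3))
        assert or2 == pytest.approx(2.0)

    def test_multiplicative_null_additive_nonnull(self):
        res = interact_epi.reri(np.array([np.log(2), np.log(2), 0.0]), 0.001 * np.eye(3))
        assert res.mult_or == pytest.approx(1.0)
        assert res.reri == pytest.approx(1.0)  # scale distinction

    def test_invalid_covariance_rejected(self):
        with pytest.raises(ValueError):
            interact_epi.reri(np.zeros(3), -np.eye(3))


class TestStratifiedORMeta:
    def test_pooling_matches_random_effects(self):
        rec = pd.DataFrame({
            "variant_id": "v", "stratum": ["GA"] * 2,
            "beta": [0.1, 0.3], "se": [0.1, 0.1], "n": [100, 100],
            "study": ["a", "b"]})
        out = interact_epi.stratified_or_meta(rec).iloc[0]
        assert out["or"] == pytest.approx(np.exp(0.2))
        assert out["Q"] == pytest.approx(2.0)


class TestSubsampleControls:
    def test_one_to_ten_ratio_counts(self):
        rng = np.random.default_rng(49)
        y = np.r_[np.ones(416), np.zeros(86_515)]
        pheno = make_pheno(len(y), rng, case_status=y.astype(int))
        sub, mask = interact_epi.subsample_controls(pheno, ratio=10, seed=1)
        assert int(sub.data["case_status"].sum()) == 416
        assert len(sub) - 416 == 4160

    def test_identity_when_ratio_exhausts_controls(self):
        rng = np.random.default_rng(50)
        y = np.r_[np.ones(50), np.zeros(500)].astype(int)
        pheno = make_pheno(len(y), rng, case_status=y)
        sub, _ = interact_epi.subsample_controls(pheno, ratio=10, seed=1)
        assert len(sub) == 550

    def test_seeds_give_different_subsets_same_size(self):
        rng = np.random.default_rng(51)
        y = np.r_[np.ones(100), np.zeros(5000)].astype(int)
        pheno = make_pheno(len(y), rng, case_status=y)
        _, m1 = interact_epi.subsample_controls(pheno, ratio=5, seed=1)
        _, m2 = interact_epi.subsample_controls(pheno, ratio=5, seed=2)
        assert m1.sum() == m2.sum()
        assert not np.array_equal(m1, m2)

    def test_insufficient_controls_rejected(self):
        rng = np.random.default_rng(52)
        y = np.r_[np.ones(100), np.zeros(150)].astype(int)
        pheno = make_pheno(len(y), rng, case_status=y)
        with pytest.raises(ValueError):
            interact_epi.subsample_controls(pheno, ratio=10, seed=1)


class TestFirthVsMLImbalance:
    def test_firth_type1_not_worse_under_imbalance(self):
        """Under a 1:50 imbalanced null, Firth's type-1 error for the SNP
        term does not exceed the ML rate."""
        from stratgwas import _stats
        rng = np.random.default_rng(53)
        n = 2000
        rej_ml = rej_firth = 0
        reps = 300
        for _ in range(reps):
            g = rng.binomial(2, 0.1, n).astype(float)
            y = np.zeros(n)
            y[rng.choice(n, 40, replace=False)] = 1  # null: cases at random
            X = np.column_stack([np.ones(n), g])
            ml = _stats.logistic_irls(X, y)
            fi = _stats.firth_logistic(X, y)
            rej_ml += abs(ml.beta[1] / ml.se[1]) > 1.96
            rej_firth += abs(fi.beta[1] / fi.se[1]) > 1.96
        assert rej_firth <= rej_ml + 2
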