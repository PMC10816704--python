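"""Shared numerical routines: log-space p-values, vectorized OLS scans,
IRLS logistic regression, and Firth penalized logistic regression.

All p-values are handled in log10 space so that extreme test statistics
(|z| of several hundred, as seen at strong-effect loci) never underflow
to zero.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

LOG10 = np.log(10.0)

# Reference medians for genomic-control: chi2 with 1 df and 2 df.
CHI2_MEDIAN_1DF = stats.chi2.median(1)  # 0.4549364...
CHI2_MEDIAN_2DF = 2.0 * np.log(2.0)     # 1.3862944...


def log10_sf_norm_twosided(z):
    """Two-sided normal log10 p-value for z-score(s), underflow safe."""
    z = np.asarray(z, dtype=float)
    return (np.log(2.0) + stats.norm.logsf(np.abs(z))) / LOG10


def log10_sf_chi2(x, df):
    """log10 survival function of chi-square with ``df`` degrees of freedom.

    scipy's ``chi2.logsf`` underflows to -inf for very large statistics, so
    df = 1 routes through the stable normal logsf and df = 2 uses the exact
    closed form sf = exp(-x/2).
    """
    x = np.asarray(x, dtype=float)
    if df == 1:
        return (np.log(2.0) + stats.norm.logsf(np.sqrt(np.maximum(x, 0.0)))) / LOG10
    if df == 2:
        return -x / 2.0 / LOG10
    return stats.chi2.logsf(x, df) / LOG10


def log10p_to_chi2(log10_p, df):
    """Invert a log10 p-value to the chi-square statistic with ``df`` df.

    For 1 df this uses the normal quantile of p/2 (stable for very small p
    via ``norm.isf`` on the log scale is not available in scipy, so values
    below ~1e-300 are computed from the asymptotic tail expansion).
    """
    lp = np.asarray(log10_p, dtype=float)
    p = np.power(10.0, np.clip(lp, -300, 0))
    if df == 1:
        z = stats.norm.isf(p / 2.0)
        chi2 = z * z
    else:
        chi2 = stats.chi2.isf(p, df)
    # tail expansion where p underflowed the clip
    tiny = lp < -300
    if np.any(tiny):
        ln_p = lp * LOG10
        if df == 1:
            # logsf(z) ~ -z^2/2 - log(z) - 0.5*log(2*pi) ; solve iteratively
            x = np.sqrt(-2.0 * (ln_p - np.log(2.0)))
            for _ in range(50):
                x = np.sqrt(-2.0 * (ln_p - np.log(2.0) + np.log(x) + 0.5 * np.log(2 * np.pi)))
            chi2 = np.where(tiny, x * x, chi2)
        elif df == 2:
            chi2 = np.where(tiny, -2.0 * ln_p, chi2)
        else:  # pragma: no cover - not used for other df
            raise ValueError("underflow inversion supported for df in {1, 2}")
    return chi2


def check_full_rank(C, names):
    """Raise ValueError naming the first collinear column of design C."""
    C = np.asarray(C, dtype=float)
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        # identify offending column by incremental rank
        r = 0
        for j in range(C.shape[1]):
            nr = np.linalg.matrix_rank(C[:, : j + 1])
            if nr == r:
                raise ValueError(f"design matrix is rank deficient: column '{names[j]}' is collinear")
            r = nr
        raise ValueError("design matrix is rank deficient")


def ols_scan(y, G, C):
    """Vectorized per-column OLS of y on each column of G, adjusting for C.

    Uses the Frisch-Waugh-Lovell projection: y and every genotype column are
    residualized on the covariate block C (which must include the intercept),
    then the per-variant slope is a simple regression on the residuals.

    Returns (beta, se, log10_p, df_resid) arrays; columns of G that are
    constant after projection get NaN estimates.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    C = np.asarray(C, dtype=float)
    n, p = C.shape
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)
    gg = np.einsum("ij,ij->j", G_r, G_r)
    gy = G_r.T @ y_r
    yy = y_r @ y_r
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg
        dof = n - p - 1
        rss = yy - beta * gy
        sigma2 = np.maximum(rss, 0.0) / dof
        se = np.sqrt(sigma2 / gg)
        t = beta / se
    log10_p = (np.log(2.0) + stats.t.logsf(np.abs(t), dof)) / LOG10
    mono = gg <= n * np.finfo(float).eps * np.maximum(1.0, np.einsum("ij,ij->j", G, G) / n)
    beta = np.where(mono, np.nan, beta)
    se = np.where(mono, np.nan, se)
    log10_p = np.where(mono, np.nan, log10_p)
    return beta, se, log10_p, dof


def ols_scan_interaction(y, G, mod, C):
    """Vectorized per-variant fit of y ~ C + mod + g + g*mod (linear model).

    C must contain the intercept; ``mod`` is the 0/1 modifier coding.
    Residualizes (y, g, g*mod) on [C, mod] and solves the remaining
    2x2 normal equations per variant.

    Returns dict of arrays: beta_snp, se_snp, beta_int, se_int,
    cov_snp_int, chi2_2df (Wald for the pair), log10_p_snp, log10_p_int,
    df_resid.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    mod = np.asarray(mod, dtype=float)
    C_full = np.column_stack([C, mod])
    n, p = C_full.shape
    Q, _ = np.linalg.qr(C_full)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)
    GM = G * mod[:, None]
    GM_r = GM - Q @ (Q.T @ GM)

    a = np.einsum("ij,ij->j", G_r, G_r)
    b = np.einsum("ij,ij->j", G_r, GM_r)
    d = np.einsum("ij,ij->j", GM_r, GM_r)
    gy = G_r.T @ y_r
    my = GM_r.T @ y_r
    yy = y_r @ y_r

    det = a * d - b * b
    with np.errstate(divide="ignore", invalid="ignore"):
        beta_snp = (d * gy - b * my) / det
        beta_int = (a * my - b * gy) / det
        dof = n - p - 2
        rss = yy - beta_snp * gy - beta_int * my
        sigma2 = np.maximum(rss, 0.0) / dof
        var_snp = sigma2 * d / det
        var_int = sigma2 * a / det
        cov = -sigma2 * b / det
        se_snp = np.sqrt(var_snp)
        se_int = np.sqrt(var_int)
        # 2-df Wald for (beta_snp, beta_int)
        chi2 = (beta_snp ** 2 * a + 2 * beta_snp * beta_int * b + beta_int ** 2 * d) / sigma2
        t_snp = beta_snp / se_snp
        t_int = beta_int / se_int
    bad = det <= 0
    for arr in (beta_snp, beta_int, se_snp, se_int, cov, chi2):
        arr[bad] = np.nan
    return {
        "beta_snp": beta_snp,
        "se_snp": se_snp,
        "beta_int": beta_int,
        "se_int": se_int,
        "cov_snp_int": cov,
        "chi2_2df": chi2,
        "log10_p_snp": (np.log(2.0) + stats.t.logsf(np.abs(t_snp), dof)) / LOG10,
        "log10_p_int": (np.log(2.0) + stats.t.logsf(np.abs(t_int), dof)) / LOG10,
        "df_resid": dof,
    }


class LogisticFit:
    """Result of an IRLS / Firth logistic fit."""

    __slots__ = ("beta", "cov", "converged", "separated", "iterations", "loglik")

    def __init__(self, beta, cov, converged, separated, iterations, loglik):
        self.beta = beta
        self.cov = cov
        self.converged = converged
        self.separated = separated
        self.iterations = iterations
        self.loglik = loglik

    @property
    def se(self):
        return np.sqrt(np.diag(self.cov))


def logistic_irls(X, y, max_iter=50, tol=1e-8):
    """Maximum-likelihood logistic regression by iteratively reweighted
    least squares, with step halving and quasi-separation detection.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome has no variation")
    n, k = X.shape
    beta = np.zeros(k)
    beta[0] = np.log(y.mean() / (1 - y.mean()))  # assumes column 0 intercept
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        XtWX = X.T @ (X * W[:, None])
        score = X.T @ (y - p)
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError:
            break
        # step halving on the log-likelihood
        for _ in range(20):
            cand = beta + step
            eta_c = X @ cand
            ll = np.sum(y * eta_c - np.logaddexp(0.0, eta_c))
            if ll >= ll_old - 1e-12:
                break
            step *= 0.5
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    W = p * (1 - p)
    XtWX = X.T @ (X * W[:, None])
    try:
        cov = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    extreme = bool(np.any((p < 1e-10) | (p > 1 - 1e-10)))
    separated = bool(np.max(np.abs(beta[1:]), initial=0.0) > 15) or (not converged and extreme)
    return LogisticFit(beta, cov, converged, separated, it, ll_old)


def firth_logistic(X, y, max_iter=100, tol=1e-8):
    """Firth bias-reduced logistic regression (Jeffreys-prior penalty).

    The modified score is U*(beta) = X'(y - p + h(1/2 - p)) where h are the
    leverages of the weighted hat matrix. Estimates remain finite under
    complete separation. Wald SEs come from the penalized information.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome has no variation")
    n, k = X.shape
    beta = np.zeros(k)
    beta[0] = np.log((y.sum() + 0.5) / (n - y.sum() + 0.5))

    def penalized_ll(b):
        eta = X @ b
        p = 1.0 / (1.0 + np.exp(-eta))
        W = np.maximum(p * (1 - p), 1e-300)
        XtWX = X.T @ (X * W[:, None])
        sign, logdet = np.linalg.slogdet(XtWX)
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        return ll + 0.5 * logdet

    ll_old = penalized_ll(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = np.maximum(p * (1 - p), 1e-300)
        rootW = np.sqrt(W)
        XW = X * rootW[:, None]
        XtWX = XW.T @ XW
        try:
            XtWX_inv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            raise RuntimeError("singular information matrix in Firth fit")
        h = np.einsum("ij,jk,ik->i", XW, XtWX_inv, XW)
        score = X.T @ (y - p + h * (0.5 - p))
        step = XtWX_inv @ score
        for _ in range(25):
            cand = beta + step
            ll = penalized_ll(cand)
            if ll >= ll_old - 1e-12:
                break
            step *= 0.5
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    if not converged:
        raise RuntimeError(f"Firth fit did not converge in {max_iter} iterations; last beta={beta}")
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    W = p * (1 - p)
    cov = np.linalg.inv(X.T @ (X * W[:, None]))
    return LogisticFit(beta, cov, converged, False, it, ll_old)
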