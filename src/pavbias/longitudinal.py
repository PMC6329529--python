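"""Test-retest statistics, Gaussianization, latent change score models, and
mixture clustering of model-fit values.

The latent change score (LCS) model treats two-wave data (x1, x2) as
x2 = x1 + Delta with the latent change Delta = alpha + beta * x1 + zeta,
zeta ~ N(0, psi).  beta (the self-feedback or proportional-change
coefficient) is the regression of change on baseline; beta = -1 corresponds
to pure regression towards the mean (x2 independent of x1).  The
just-identified univariate LCS is equivalent to an unconstrained bivariate
normal, so its ML estimates reproduce the sample moments exactly; nested
comparisons against (a) the regression-to-mean-only model (beta fixed at -1)
and (b) an equal-mean/equal-variance model use likelihood-ratio chi-square
tests and BIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

#: default correlation type per fitted measure: Spearman for skewed
#: natural-scale quantities, Pearson for approximately Gaussian ones.
DEFAULT_RETEST_METHODS = {
    "b_pav": "spearman", "lam": "spearman", "lam_app": "spearman",
    "lam_av": "spearman", "xi": "spearman",
    "rho": "pearson", "rho_app": "pearson", "rho_av": "pearson",
    "b_go": "pearson", "il": "pearson",
}


def retest_statistics(table1: pd.DataFrame, table2: pd.DataFrame,
                      methods: dict | None = None,
                      default_method: str = "spearman") -> pd.DataFrame:
    """Per-measure test-retest correlation and paired change tests.

    Tables are indexed by participant id with one column per measure;
    participants are matched on the index.  The Bonferroni factor is the
    number of shared measures.
    """
    common_ids = table1.index.intersection(table2.index)
    if len(common_ids) < 10:
        raise ValueError(f"need >= 10 matched participants, got {len(common_ids)}")
    measures = [c for c in table1.columns if c in table2.columns]
    if not measures:
        raise ValueError("no shared measures between the tables")
    methods = {**DEFAULT_RETEST_METHODS, **(methods or {})}
    m = len(measures)
    rows = []
    for col in measures:
        x = table1.loc[common_ids, col].to_numpy(dtype=float)
        y = table2.loc[common_ids, col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        method = methods.get(col, default_method)
        if method == "pearson":
            r, rp = stats.pearsonr(x, y)
        else:
            r, rp = stats.spearmanr(x, y)
        diff = y - x
        if np.allclose(diff, 0):
            wp = 1.0
        else:
            wp = float(stats.wilcoxon(diff[diff != 0]).pvalue)
        rows.append({
            "measure": col, "method": method, "n": int(ok.sum()),
            "r": float(r), "r_p": float(rp),
            "median_change": float(np.median(diff)), "change_p": wp,
            "change_p_bonferroni": min(1.0, m * wp),
        })
    return pd.DataFrame(rows).set_index("measure")


def gaussianize(values) -> np.ndarray:
    """Rank-preserving map to a Gaussian with the input's mean and SD.

    The empirical CDF is evaluated with a 1/(n+1) offset (average ranks for
    ties), pushed through the inverse normal CDF, and rescaled so the output
    matches the input's mean and SD exactly.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 10:
        raise ValueError("need a 1-d vector with n >= 10")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("constant vector cannot be Gaussianized")
    ranks = stats.rankdata(x, method="average")
    z = stats.norm.ppf(ranks / (x.size + 1))
    z = (z - z.mean()) / z.std()
    return x.mean() + x.std() * z


# ---------------------------------------------------------------------------
# latent change score model

@dataclass
class LcsResult:
    beta: float
    alpha: float
    change_mean: float
    change_var: float
    residual_var: float
    mu1: float
    var1: float
    loglik: float
    bic: float
    n: int
    implied_mean: np.ndarray
    implied_cov: np.ndarray
    chi2_rtm: float          # vs beta = -1 (regression-to-mean only)
    p_rtm: float
    bic_rtm: float
    chi2_nochange: float     # vs equal mean & variance across waves
    p_nochange: float
    bic_nochange: float


def _bvn_loglik(x1, x2, mean, cov) -> float:
    cov = np.asarray(cov, dtype=float)
    # guard against degenerate (zero-variance) components
    jitter = 1e-12 * max(1.0, np.trace(cov))
    cov = cov + jitter * np.eye(2)
    return float(np.sum(stats.multivariate_normal.logpdf(
        np.column_stack([x1, x2]), mean=mean, cov=cov, allow_singular=True)))


def fit_lcs(x1, x2) -> LcsResult:
    """ML fit of the just-identified univariate LCS with nested comparisons."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("x1 and x2 must be matched 1-d vectors")
    if x1.size < 30:
        raise ValueError("need n >= 30 matched pairs")
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
        raise ValueError("inputs contain non-finite values")
    n = x1.size
    mu1, mu2 = x1.mean(), x2.mean()
    v1 = x1.var()
    v2 = x2.var()
    c12 = np.mean((x1 - mu1) * (x2 - mu2))
    # moment-matching = ML for the just-identified model
    beta = c12 / v1 - 1.0
    psi = max(v2 - (1.0 + beta) ** 2 * v1, 0.0)
    alpha = mu2 - mu1 - beta * mu1
    mean_ji = np.array([mu1, mu2])
    cov_ji = np.array([[v1, c12], [c12, v2]])
    ll_ji = _bvn_loglik(x1, x2, mean_ji, cov_ji)
    bic_ji = -2 * ll_ji + 5 * np.log(n)

    # (a) pure regression to the mean: beta = -1 -> x2 independent of x1
    ll_rtm = _bvn_loglik(x1, x2, np.array([mu1, mu2]),
                         np.array([[v1, 0.0], [0.0, v2]]))
    chi2_rtm = max(0.0, 2 * (ll_ji - ll_rtm))
    p_rtm = float(stats.chi2.sf(chi2_rtm, df=1))
    bic_rtm = -2 * ll_rtm + 4 * np.log(n)

    # (b) equal mean and variance across waves, covariance free
    def nll_eq(params):
        mu, logv, z = params
        v = np.exp(logv)
        r = np.tanh(z)
        cov = np.array([[v, r * v], [r * v, v]])
        return -_bvn_loglik(x1, x2, np.array([mu, mu]), cov)

    pooled_v = 0.5 * (v1 + v2)
    r0 = np.clip(c12 / pooled_v, -0.99, 0.99)
    res = optimize.minimize(nll_eq,
                            np.array([0.5 * (mu1 + mu2), np.log(pooled_v),
                                      np.arctanh(r0)]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10,
                                     "maxiter": 2000})
    ll_eq = -float(res.fun)
    chi2_eq = max(0.0, 2 * (ll_ji - ll_eq))
    p_eq = float(stats.chi2.sf(chi2_eq, df=2))
    bic_eq = -2 * ll_eq + 3 * np.log(n)

    return LcsResult(
        beta=float(beta), alpha=float(alpha),
        change_mean=float(mu2 - mu1),
        change_var=float(v1 + v2 - 2 * c12),
        residual_var=float(psi), mu1=float(mu1), var1=float(v1),
        loglik=ll_ji, bic=float(bic_ji), n=n,
        implied_mean=mean_ji, implied_cov=cov_ji,
        chi2_rtm=float(chi2_rtm), p_rtm=p_rtm, bic_rtm=float(bic_rtm),
        chi2_nochange=float(chi2_eq), p_nochange=p_eq,
        bic_nochange=float(bic_eq))


# ---------------------------------------------------------------------------
# mixture clustering of model fit

@dataclass
class ClusterModel:
    k: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    assignments: np.ndarray
    bic_by_k: dict
    sizes: np.ndarray


def cluster_fit_values(il1, il2, k_candidates=range(1, 7), n_init: int = 20,
                       seed: int = 0, reg_covar: float = 1e-6) -> ClusterModel:
    """Full-covariance Gaussian mixture over the joint (wave-1, wave-2)
    model-fit values; the number of components is selected by BIC."""
    il1 = np.asarray(il1, dtype=float)
    il2 = np.asarray(il2, dtype=float)
    if il1.shape != il2.shape or il1.ndim != 1:
        raise ValueError("il1 and il2 must be matched 1-d vectors")
    if il1.size < 50:
        raise ValueError("need n >= 50 matched pairs")
    X = np.column_stack([il1, il2])
    best, bics = None, {}
    for k in k_candidates:
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             n_init=n_init, random_state=seed,
                             reg_covar=reg_covar)
        gm.fit(X)
        bics[k] = float(gm.bic(X))
        if best is None or bics[k] < bics[best[0]]:
            best = (k, gm)
    k, gm = best
    labels = gm.predict(X)
    return ClusterModel(
        k=k, weights=gm.weights_, means=gm.means_,
        covariances=gm.covariances_, assignments=labels,
        bic_by_k=bics, sizes=np.bincount(labels, minlength=k))
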