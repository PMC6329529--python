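"""Hierarchical type-2 maximum-likelihood fitting by expectation-maximization.

Each wave is fitted independently.  Subject-level parameters theta live in
transformed space with an independent Gaussian population prior
N(mu_k, sigma_k^2) per parameter (the "macro" parameters Theta).  The E-step
finds each subject's MAP estimate of log-likelihood + log-prior (multi-start
quasi-Newton) together with the local Laplace curvature; the M-step updates
the prior mean to the mean of the MAP estimates and the prior variance to
their variance plus the mean inverse-Hessian diagonal (floored away from
collapse).  Model evidence is summarized per subject by the integrated
likelihood

    iL = ln Integral p(d | theta, M) p(theta | Theta) dtheta,

estimated by Monte-Carlo sampling from the fitted prior, and at the group
level by the integrated BIC

    iBIC = -2 sum iL + N_par ln(n_tr n_pt),

where N_par counts the population means and variances (2 per subject-level
parameter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from ._kernels import batch_session_nll, session_nll
from .models import ModelSpec, get_model, session_log_likelihood, transform_params
from .task import Cohort, SessionData, N_TRIALS

from scipy.special import expit as _SIGMOID

#: box for transformed subject-level parameters during optimization; wide
#: enough to be non-informative, tight enough to keep exp() finite
_THETA_BOUND = 20.0


class FitError(RuntimeError):
    pass


@dataclass
class PopulationPrior:
    """Diagonal Gaussian over transformed subject-level parameters."""

    model: ModelSpec
    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self):
        self.model = get_model(self.model)
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        d = self.model.n_subject_params
        if self.mean.shape != (d,) or self.var.shape != (d,):
            raise ValueError(f"prior moments must have length {d}")
        if np.any(self.var <= 0):
            raise ValueError("prior variances must be > 0")


@dataclass
class SubjectFit:
    participant_id: str
    theta: np.ndarray            # MAP transformed parameters
    hess_inv_diag: np.ndarray    # Laplace curvature at the MAP
    log_posterior: float
    log_likelihood: float
    il: float                    # integrated likelihood (nats)
    il_se: float
    per_trial_p: np.ndarray      # prediction probability per responded trial
    flags: list = field(default_factory=list)

    def params_natural(self, model) -> dict:
        return transform_params(self.theta, model, "to_natural")


@dataclass
class CohortFit:
    model: ModelSpec
    prior: PopulationPrior
    subjects: list
    ibic: float
    n_trials: int
    trace: list
    converged: bool
    seed: int

    @property
    def il_total(self) -> float:
        return float(sum(s.il for s in self.subjects))

    def theta_matrix(self) -> np.ndarray:
        return np.array([s.theta for s in self.subjects])

    def parameter_table(self):
        import pandas as pd

        model = get_model(self.model)
        rows = []
        for s in self.subjects:
            row = {"participant_id": s.participant_id, "il": s.il,
                   "il_se": s.il_se}
            nat = s.params_natural(model)
            for p, t in zip(model.params, s.theta):
                row[p] = nat[p]
                row[f"theta_{p}"] = t
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# transformed theta -> unified kernel parameter matrix

def _kernel_matrix(thetas: np.ndarray, model: ModelSpec) -> np.ndarray:
    """(B, n_subject_params) transformed matrix -> (B, 8) natural kernel matrix."""
    T = np.clip(np.atleast_2d(thetas), -_THETA_BOUND, _THETA_BOUND)
    B = T.shape[0]
    P = np.empty((B, 8))
    if model.base == "valenced_learning":
        P[:, 0] = P[:, 1] = np.exp(T[:, 0])
        P[:, 2] = _SIGMOID(T[:, 1])
        P[:, 3] = _SIGMOID(T[:, 2])
    elif model.base == "valenced_sensitivity":
        P[:, 0] = np.exp(T[:, 0])
        P[:, 1] = np.exp(T[:, 1])
        P[:, 2] = P[:, 3] = _SIGMOID(T[:, 2])
    else:  # sensitivity_ratio: kappa = ln rho_av - ln rho_app
        P[:, 0] = np.exp(T[:, 0])
        P[:, 1] = np.exp(T[:, 0] + T[:, 1])
        P[:, 2] = P[:, 3] = _SIGMOID(T[:, 2])
    P[:, 4] = T[:, 3]
    P[:, 5] = np.exp(T[:, 4])
    P[:, 6] = _SIGMOID(T[:, 5])
    P[:, 7] = _SIGMOID(T[:, 6]) if model.forgetting else 1.0
    return P


def _session_arrays(session: SessionData, skip=()):
    mask = np.ones(session.n_trials, dtype=bool)
    for idx in skip:
        mask[idx - 1] = False
    return (session.stimulus.astype(np.int64),
            session.condition.astype(np.int64),
            session.action.astype(np.int64),
            session.outcome.astype(np.int64),
            mask)


def session_nll_batch(thetas, session, model, skip=(), decay_v=False):
    """Negative log-likelihoods for a batch of transformed parameter vectors."""
    model = get_model(model)
    stim, cond, act, out, mask = _session_arrays(session, skip)
    P = _kernel_matrix(np.atleast_2d(thetas), model)
    return batch_session_nll(P, model.forgetting, decay_v, stim, cond, act,
                             out, mask)


# ---------------------------------------------------------------------------
# subject-level MAP

def _neg_log_post_and_grad(theta, arrays, model, mu, var, h=1e-4):
    """Objective nll + Gaussian penalty, gradient by central differences on
    the likelihood term (one batched kernel call) plus the analytic prior part."""
    stim, cond, act, out, mask = arrays
    d = theta.size
    pts = np.tile(theta, (2 * d + 1, 1))
    for i in range(d):
        pts[1 + 2 * i, i] += h
        pts[2 + 2 * i, i] -= h
    P = _kernel_matrix(pts, model)
    nll = batch_session_nll(P, model.forgetting, False, stim, cond, act, out,
                            mask)
    g_lik = (nll[1::2] - nll[2::2]) / (2 * h)
    resid = (theta - mu) / var
    f = nll[0] + 0.5 * np.sum((theta - mu) ** 2 / var)
    return f, g_lik + resid


def _numeric_hessian(fun, theta, h=5e-3):
    d = theta.size
    pts = [theta]
    for i in range(d):
        for s in (h, -h):
            p = theta.copy()
            p[i] += s
            pts.append(p)
    for i in range(d):
        for j in range(i + 1, d):
            for si, sj in ((h, h), (h, -h), (-h, h), (-h, -h)):
                p = theta.copy()
                p[i] += si
                p[j] += sj
                pts.append(p)
    vals = fun(np.array(pts))
    H = np.empty((d, d))
    f0 = vals[0]
    for i in range(d):
        fp, fm = vals[1 + 2 * i], vals[2 + 2 * i]
        H[i, i] = (fp - 2 * f0 + fm) / h ** 2
    k = 1 + 2 * d
    for i in range(d):
        for j in range(i + 1, d):
            fpp, fpm, fmp, fmm = vals[k:k + 4]
            k += 4
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h ** 2)
    return H


def _fit_subject(session, model, prior, starts, skip=()):
    """MAP + Laplace curvature for one subject; returns best of the starts."""
    arrays = _session_arrays(session, skip)
    mu, var = prior.mean, prior.var
    best = None
    for x0 in starts:
        res = minimize(_neg_log_post_and_grad, x0,
                       args=(arrays, model, mu, var), jac=True,
                       method="L-BFGS-B",
                       bounds=[(-_THETA_BOUND, _THETA_BOUND)] * len(x0),
                       options={"maxiter": 200, "ftol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    flags = []
    if not best.success:
        flags.append(f"optimizer: {best.message}")

    def nll_only(pts):
        P = _kernel_matrix(pts, model)
        return batch_session_nll(P, model.forgetting, False, *arrays)

    H = _numeric_hessian(nll_only, theta) + np.diag(1.0 / var)
    try:
        Hinv = np.linalg.inv(H)
        diag = np.diag(Hinv)
        if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
            raise np.linalg.LinAlgError("non-PD curvature")
    except np.linalg.LinAlgError:
        diag = 1.0 / np.maximum(np.diag(H), 1e-3)
        flags.append("singular Hessian: fell back to diagonal curvature")
    nll_theta = float(nll_only(theta[None, :])[0])
    log_post = -(nll_theta + 0.5 * np.sum((theta - mu) ** 2 / var)
                 + 0.5 * np.sum(np.log(2 * np.pi * var)))
    return theta, np.abs(diag), log_post, -nll_theta, flags


# ---------------------------------------------------------------------------
# integrated likelihood

def integrated_likelihood(session, prior: PopulationPrior, model=None,
                          n_samples: int = 2000, seed: int = 0, skip=()):
    """Monte-Carlo estimate of ln Integral p(d|theta) N(theta; mu, sigma^2) dtheta.

    Returns ``(iL, se)`` with the SE from the delta method on the
    log-mean-exp.  Computed wholly in log space, so underflow of individual
    samples cannot produce -inf unless every sample underflows.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    model = get_model(model or prior.model)
    rng = np.random.default_rng(seed)
    d = model.n_subject_params
    thetas = prior.mean + np.sqrt(prior.var) * rng.standard_normal((n_samples, d))
    ll = -session_nll_batch(thetas, session, model, skip=skip)
    il = float(logsumexp(ll) - np.log(n_samples))
    w = np.exp(ll - ll.max())
    se = float(np.std(w) / (np.mean(w) * np.sqrt(n_samples)))
    return il, se


def ibic_penalty(n_subject_params: int, n_pt: int, n_tr: int = N_TRIALS) -> float:
    return 2 * n_subject_params * np.log(n_tr * n_pt)


def ibic(fit: CohortFit) -> float:
    """iBIC = -2 sum iL + N_par ln(n_tr n_pt), N_par = 2 x subject params."""
    model = get_model(fit.model)
    return float(-2.0 * fit.il_total
                 + ibic_penalty(model.n_subject_params, len(fit.subjects),
                                fit.n_trials))


# ---------------------------------------------------------------------------
# EM driver

def fit_em(cohort: Cohort, model, max_iter: int = 200, tol: float = 1e-3,
           n_restarts: int = 4, seed: int = 0, n_il_samples: int = 2000,
           variance_floor: float = 1e-6, init_mean=None, init_var=None,
           prior_family: str = "gaussian_transformed",
           verbose: bool = False) -> CohortFit:
    """Hierarchical EM fit of one cohort (one wave) under one model.

    E-step: per-subject MAP of log-likelihood + log-prior with multi-start
    L-BFGS (restarts jittered around the prior mean on the first iteration,
    warm-started thereafter) and numeric Laplace curvature.  M-step: prior
    mean <- mean(theta-hat); prior variance <- var(theta-hat) + mean
    inverse-Hessian diagonal, floored at ``variance_floor``.  Iterates until
    the transformed prior means move less than ``tol`` (max-abs) or
    ``max_iter``.  Deterministic given ``seed``.
    """
    if prior_family != "gaussian_transformed":
        raise ValueError(
            "fit_em fits a Gaussian prior in transformed space; alternative "
            "population families are generator-side robustness settings")
    model = get_model(model)
    if len(cohort) < 2:
        raise FitError("need at least 2 participants for a hierarchical fit")
    d = model.n_subject_params
    mean = np.zeros(d) if init_mean is None else np.asarray(init_mean, float)
    var = np.full(d, 4.0) if init_var is None else np.asarray(init_var, float)
    rng = np.random.default_rng(seed)
    thetas = None
    trace = []
    converged = False
    prev_sum_lp = -np.inf
    for it in range(max_iter):
        prior = PopulationPrior(model=model, mean=mean, var=var)
        new_thetas, inv_diags, log_posts, log_liks, all_flags = [], [], [], [], []
        for i, session in enumerate(cohort):
            if it == 0:
                starts = [mean] + [mean + rng.normal(0, 1, d)
                                   for _ in range(max(0, n_restarts - 1))]
            else:
                starts = [thetas[i], mean]
            th, diag, lp, ll, flags = _fit_subject(session, model, prior,
                                                   starts)
            new_thetas.append(th)
            inv_diags.append(diag)
            log_posts.append(lp)
            log_liks.append(ll)
            all_flags.append(flags)
        thetas = new_thetas
        T = np.array(thetas)
        new_mean = T.mean(axis=0)
        new_var = np.maximum(T.var(axis=0) + np.mean(inv_diags, axis=0),
                             variance_floor)
        sum_lp = float(np.sum(log_posts))
        delta = float(np.max(np.abs(new_mean - mean)))
        trace.append({"iter": it, "mean": new_mean.copy(),
                      "var": new_var.copy(), "sum_log_post": sum_lp,
                      "max_delta_mean": delta})
        if verbose:
            print(f"EM iter {it}: sum log-post {sum_lp:.2f}, "
                  f"max |delta mu| {delta:.4f}")
        if it > 0 and sum_lp < prev_sum_lp - 1e-6:
            warnings.warn(
                f"EM iteration {it}: sum log-posterior decreased "
                f"({prev_sum_lp:.3f} -> {sum_lp:.3f})", RuntimeWarning)
        prev_sum_lp = sum_lp
        mean, var = new_mean, new_var
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"EM did not converge within {max_iter} iterations "
                      f"(last max |delta mu| = {delta:.2e})", RuntimeWarning)

    prior = PopulationPrior(model=model, mean=mean, var=var)
    il_seeds = np.random.SeedSequence(seed).generate_state(len(cohort))
    subjects = []
    for i, session in enumerate(cohort):
        il, il_se = integrated_likelihood(
            session, prior, model, n_samples=n_il_samples,
            seed=int(il_seeds[i]))
        nat = transform_params(thetas[i], model, "to_natural")
        _, per_trial = session_log_likelihood(session, nat, model)
        subjects.append(SubjectFit(
            participant_id=session.participant_id, theta=thetas[i],
            hess_inv_diag=inv_diags[i], log_posterior=log_posts[i],
            log_likelihood=log_liks[i], il=il, il_se=il_se,
            per_trial_p=np.exp(per_trial), flags=all_flags[i]))
    fit = CohortFit(model=model, prior=prior, subjects=subjects, ibic=np.nan,
                    n_trials=cohort.sessions[0].n_trials, trace=trace,
                    converged=converged, seed=seed)
    fit.ibic = ibic(fit)
    return fit
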