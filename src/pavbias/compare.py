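"""Model comparison: iBIC differences, per-trial prediction probability,
protected exceedance probabilities, and the left-out-likelihood procedure.

The left-out-likelihood (LOL) comparison scores models by their predictive
likelihood on trials excluded from fitting.  A "group training" subsample
provides the population prior per model; each remaining test subject's
posterior over transformed parameters is then sampled by MCMC using the
log-posterior over included trials only (left-out trials' realized actions
and outcomes still drive value learning - the "informed" handling - but
contribute no likelihood), and the left-out trials' likelihood is averaged
over the posterior samples.  Paired per-subject differences between models
are summarized by the median difference in prediction probability per trial
(Ppt) with a bootstrap confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, logsumexp
from scipy.stats import wilcoxon

from .emfit import (CohortFit, PopulationPrior, fit_em, session_nll_batch)
from .models import get_model
from .task import Cohort


# ---------------------------------------------------------------------------
# iBIC comparison

def compare_ibic(fit_a: CohortFit, fit_b: CohortFit) -> dict:
    """Delta iBIC (B - A; positive favours A) with per-subject iL differences
    and a paired Wilcoxon signed-rank test."""
    ids_a = [s.participant_id for s in fit_a.subjects]
    ids_b = [s.participant_id for s in fit_b.subjects]
    if ids_a != ids_b:
        diff = sorted(set(ids_a) ^ set(ids_b))
        raise ValueError(f"fits cover different participants: {diff[:10]}")
    il_a = np.array([s.il for s in fit_a.subjects])
    il_b = np.array([s.il for s in fit_b.subjects])
    delta_il = il_a - il_b
    if np.allclose(delta_il, 0):
        stat, p = 0.0, 1.0
    else:
        stat, p = wilcoxon(delta_il, zero_method="wilcox",
                           correction=True)
    return {
        "delta_ibic": float(fit_b.ibic - fit_a.ibic),
        "delta_il": delta_il,
        "wilcoxon_stat": float(stat),
        "wilcoxon_p": float(p),
    }


def ppt(il: float, n_trials_counted: int) -> float:
    """Prediction probability per trial: the geometric-mean per-trial
    probability implied by a log-likelihood over ``n_trials_counted`` trials."""
    if il > 0:
        raise ValueError("log-likelihood must be <= 0")
    return float(np.exp(il / n_trials_counted))


# ---------------------------------------------------------------------------
# random-effects Bayesian model selection (protected exceedance)

def protected_exceedance(il_matrix, alpha0: float = 1.0, n_draws: int = 200_000,
                         seed: int = 0, max_iter: int = 500, tol: float = 1e-8):
    """Protected exceedance probabilities from a subjects x models matrix of
    log model evidences (integrated likelihoods).

    Uses the standard variational Dirichlet scheme for random-effects model
    frequencies, exceedance probabilities by Monte-Carlo over the Dirichlet
    posterior, and the protection correction
    ``pxp = ep * (1 - bor) + bor / K`` where ``bor`` is the posterior
    probability that model frequencies are indistinguishable.
    """
    L = np.asarray(il_matrix, dtype=float)
    if L.ndim != 2 or L.shape[1] < 2:
        raise ValueError("need a subjects x models matrix with >= 2 models")
    n, K = L.shape
    alpha = np.full(K, alpha0)
    for _ in range(max_iter):
        w = L + digamma(alpha) - digamma(alpha.sum())
        u = np.exp(w - logsumexp(w, axis=1, keepdims=True))
        new_alpha = alpha0 + u.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    # exceedance probabilities
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_draws)
    ep = np.bincount(np.argmax(draws, axis=1), minlength=K) / n_draws
    # Bayes omnibus risk: H0 (equal frequencies) vs H1 (Dirichlet)
    f0 = float(np.sum(logsumexp(L, axis=1) - np.log(K)))
    f1 = _dirichlet_free_energy(L, u, alpha, alpha0)
    bor = 1.0 / (1.0 + np.exp(f1 - f0))
    pxp = ep * (1.0 - bor) + bor / K
    return {"pxp": pxp, "ep": ep, "alpha": alpha, "bor": float(bor),
            "model_freq": alpha / alpha.sum()}


def _dirichlet_free_energy(L, u, alpha, alpha0):
    K = L.shape[1]
    dg = digamma(alpha) - digamma(alpha.sum())
    e_log = float(np.sum(u * (L + dg)))
    ent_u = -float(np.sum(u * np.log(np.maximum(u, 1e-300))))
    ln_b_alpha = float(np.sum(gammaln(alpha)) - gammaln(alpha.sum()))
    ln_b_alpha0 = float(K * gammaln(alpha0) - gammaln(K * alpha0))
    kl = (float(np.dot(alpha - alpha0, dg)) - ln_b_alpha + ln_b_alpha0)
    return e_log + ent_u - kl


# ---------------------------------------------------------------------------
# left-out-likelihood procedure

@dataclass
class LolConfig:
    train_size: int = 300
    left_out: tuple = (48, 96)       # 1-based, session-global trial indices
    n_walkers: int = 16
    n_steps: int = 750               # post-warmup draws per walker
    n_warmup: int = 250
    seed: int = 0
    handling: str = "informed"
    rhat_threshold: float = 1.1
    n_boot: int = 10_000
    fit_kwargs: dict = field(default_factory=dict)


@dataclass
class LolResult:
    models: list
    participant_ids: list
    lol: np.ndarray                 # test subjects x models
    ppt: np.ndarray                 # test subjects x models
    delta_ppt: np.ndarray           # model 0 minus model 1, per subject
    median_delta_ppt: float
    ci_low: float
    ci_high: float
    grand_mean_ppt: float
    excluded: list
    priors: list


def subject_lol(session, prior: PopulationPrior, left_out, config: LolConfig,
                seed: int):
    """Posterior-averaged left-out log-likelihood for one subject.

    Samples the posterior over transformed parameters given the included
    trials (emcee ensemble sampler, vectorized log-probability), then
    log-mean-exp of the left-out trials' log-likelihood over the samples.
    Returns ``(lol, rhat)``.
    """
    import emcee

    model = get_model(prior.model)
    d = model.n_subject_params
    left_out = tuple(left_out)
    include_skip = left_out                       # excluded from the target
    lo_mask_skip = tuple(i for i in range(1, session.n_trials + 1)
                         if i not in left_out)    # keep only left-out trials

    def log_prob(thetas):
        nll = session_nll_batch(thetas, session, model, skip=include_skip)
        prior_term = 0.5 * np.sum((thetas - prior.mean) ** 2 / prior.var,
                                  axis=1)
        return -(nll + prior_term)

    rng = np.random.default_rng(seed)
    # start walkers from the subject's Laplace approximation so the short
    # warmup only has to mix locally, not travel from the broad prior
    from .emfit import _fit_subject

    theta0, inv_diag, _, _, _ = _fit_subject(session, model, prior,
                                             [prior.mean], skip=include_skip)
    p0 = theta0 + np.sqrt(np.minimum(inv_diag, prior.var)) * \
        rng.standard_normal((config.n_walkers, d))
    sampler = emcee.EnsembleSampler(config.n_walkers, d, log_prob,
                                    vectorize=True)
    state = sampler.run_mcmc(p0, config.n_warmup, skip_initial_state_check=True)
    sampler.reset()
    sampler.run_mcmc(state, config.n_steps, skip_initial_state_check=True)
    chain = sampler.get_chain()                  # (steps, walkers, d)
    rhat = _split_rhat(chain)
    flat = chain.reshape(-1, d)
    lo_ll = -session_nll_batch(flat, session, model, skip=lo_mask_skip)
    lol = float(logsumexp(lo_ll) - np.log(lo_ll.size))
    return lol, rhat


def _split_rhat(chain, n_segments: int = 4) -> float:
    """Max split-R-hat across parameters for an ensemble chain.

    Walkers of an affine-invariant ensemble are not independent chains, so
    the ensemble is pooled per time segment and R-hat compares the segments -
    a stationarity check on the whole ensemble.
    """
    steps, walkers, d = chain.shape
    seg_len = steps // n_segments
    segs = np.stack([
        chain[i * seg_len:(i + 1) * seg_len].reshape(-1, d)
        for i in range(n_segments)
    ])                                          # (m, seg_len * walkers, d)
    n = segs.shape[1]
    means = segs.mean(axis=1)                   # (m, d)
    variances = segs.var(axis=1, ddof=1)
    W = variances.mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    return float(np.nanmax(rhat))


def bootstrap_ci_median(x, n_boot: int = 10_000, seed: int = 0,
                        level: float = 0.95):
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    meds = np.median(x[idx], axis=1)
    lo, hi = np.percentile(meds, [50 * (1 - level), 100 - 50 * (1 - level)])
    return float(lo), float(hi)


def split_cohort(cohort: Cohort, train_size: int, seed: int):
    """Deterministic shuffled split into group-training and test sets."""
    if train_size >= len(cohort):
        raise ValueError(f"training size {train_size} must be smaller than "
                         f"the cohort ({len(cohort)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cohort))
    ids = np.array(cohort.participant_ids)
    return (cohort.subset(ids[order[:train_size]]),
            cohort.subset(ids[order[train_size:]]))


def lol_compare(cohort: Cohort, models, config: LolConfig | None = None,
                priors=None) -> LolResult:
    """Full out-of-sample comparison of two (or more) models.

    Fits the population prior per model on the training split (unless
    ``priors`` are supplied), samples each test subject's posterior from the
    included trials, and scores each model by the left-out trials'
    posterior-averaged likelihood.  The headline statistic is the median
    per-subject difference in Ppt between the first two models with a
    bootstrap CI.
    """
    config = config or LolConfig()
    models = [get_model(m) for m in models]
    train, test = split_cohort(cohort, config.train_size, config.seed)
    if priors is None:
        priors = []
        for m in models:
            fit = fit_em(train, m, seed=config.seed, **config.fit_kwargs)
            priors.append(fit.prior)
    n_lo = len(config.left_out)
    seeds = np.random.SeedSequence(config.seed).generate_state(
        len(test) * len(models)).reshape(len(test), len(models))
    lol = np.empty((len(test), len(models)))
    excluded = []
    for i, session in enumerate(test):
        for j, m in enumerate(models):
            val, rhat = subject_lol(session, priors[j], config.left_out,
                                    config, int(seeds[i, j]))
            lol[i, j] = val
            if rhat > config.rhat_threshold:
                excluded.append((session.participant_id, m.name, rhat))
    ppt_mat = np.exp(lol / n_lo)
    delta = ppt_mat[:, 0] - ppt_mat[:, 1]
    bad_ids = {pid for pid, _, _ in excluded}
    keep = np.array([s.participant_id not in bad_ids for s in test])
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} test subjects with "
                      f"split-R-hat > {config.rhat_threshold}", RuntimeWarning)
    used = delta[keep] if keep.any() else delta
    lo, hi = bootstrap_ci_median(used, n_boot=config.n_boot, seed=config.seed)
    return LolResult(
        models=[m.name for m in models],
        participant_ids=[s.participant_id for s in test],
        lol=lol, ppt=ppt_mat, delta_ppt=delta,
        median_delta_ppt=float(np.median(used)),
        ci_low=lo, ci_high=hi,
        grand_mean_ppt=float(ppt_mat[keep].mean()) if keep.any()
        else float(ppt_mat.mean()),
        excluded=excluded, priors=priors)
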