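# Methods

This note documents the models, algorithms, default parameters and
numerical choices implemented in `pavbias`, and the limits of what its
synthetic-data studies can show.

## Task and data model

A session is 144 trials: 4 stimuli × 36 presentations in uniformly random
order, one stimulus per condition (G2W, NG2W, G2AL, NG2AL).  The correct
action (Go for G2W/G2AL, NoGo otherwise) yields the better outcome with
probability 0.8 (feedback validity); win trials pay +1/0, avoid-loss trials
0/−1.  Outcomes are coded −1/0/+1 — monetary magnitudes are absorbed into
the exchange rate ρ.  Trial indices are 1-based and session-global (the
out-of-sample procedure names the 48th and 96th trials).  Missing responses
are retained as rows so that trial alignment and left-out-trial indexing
survive; they are excluded from all likelihoods and from accuracy
denominators.  The canonical interchange format is long CSV; a MAT-v5 ZIP
reader with a configurable field map handles per-subject container files
whose internal layout must be confirmed against the files in hand.

## The model family

All variants share: Rescorla-Wagner updates of instrumental values Q(a,s)
and Pavlovian values V(s) toward ρ_v·r with rate λ_v; propensities
q(go) = Q(go,s) + b_go + b_pav·V(s) and q(nogo) = Q(nogo,s); and a
lapse-contaminated softmax p = (1−ξ)·softmax(q) + ξ/2 (computed with
max-subtraction).  Assumptions worth making explicit:

- **Initial values** Q = V = 0: returns are relative to "nothing", and the
  prior expectation of an unknown stimulus is neutral.
- **V updates on every responded trial**, regardless of the action taken:
  the Pavlovian value tracks the stimulus-outcome stream, not the policy.
- **Biases apply to Go only** — NoGo is the comparator.
- **Forgetting variants**: on each responded trial, Q entries of all
  state-action pairs except the realized one decay toward 0 by retention
  factor m (values drift back to indifference during non-presentation).
  Whether V decays too is a toggle, default off (Q-only).
- **Missing responses**: no update, no likelihood term.

Parameter transforms for fitting: log for ρ (all sensitivities) and b_pav
(assumed positive); logit for λ, ξ, m; identity for b_go and for the
sensitivity log-ratio κ = ln ρ_av − ln ρ_app.  The sensitivity-ratio model
is individually identical to valenced-sensitivity (a property test asserts
equality of likelihoods); it differs only in which quantities get
independent population priors.

The likelihood is implemented twice: a readable pure-Python reference and a
numba-compiled kernel used by EM and MCMC.  A dual-route test holds them to
1e-9 agreement on random sessions including missing responses.

## Hierarchical EM (type-2 ML)

Waves are fitted independently.  The population prior is an independent
Gaussian per transformed parameter.

- **E-step**: per-subject MAP of log-likelihood + log-prior by L-BFGS-B
  (box ±20 in transformed space, which also keeps `exp` finite), gradients
  by central differences batched through the kernel (h = 1e-4).  Four
  jittered starts around the prior mean on the first iteration; warm starts
  (previous MAP + prior mean) thereafter.  Curvature is the numeric Hessian
  of the negative log-likelihood (h = 5e-3) plus the exact prior precision;
  a non-positive-definite case falls back to the regularized diagonal and
  flags the subject.
- **M-step**: prior mean ← mean of MAPs; prior variance ← variance of MAPs
  plus the mean inverse-Hessian diagonal, floored at 1e-6 (prevents prior
  collapse on weakly identified parameters).
- **Convergence**: max |Δ mean| < 1e-3 (default) or 200 iterations.  The
  summed log-posterior is tracked and decreases trigger warnings; with MAP
  and Laplace approximations the ascent is not guaranteed to be exact, and
  occasional sub-nat decreases near convergence are normal.
- **Integrated likelihood**: log-mean-exp of session log-likelihoods at
  draws from the fitted prior (default 2000; per-subject fixed sub-seeds),
  with a delta-method standard error.  iBIC uses
  N_par = 2 × n_subject_params (a mean and a variance per parameter) and
  n_tr = 144.

**Known limitation — the small-bias information floor.**  At 144 trials,
agents whose Pavlovian bias is below roughly 0.05 are indistinguishable:
the likelihood is flat in log b_pav below about −3, those subjects' MAPs
collapse to the prior mean, and because the collapse is one-sided the
fitted population mean of log b_pav comes out roughly +0.4 too high under
the default population (verified to be an information limit, not an
optimizer artifact: MAP at the oracle prior shows the same asymmetric
shrinkage and single-parameter likelihood profiles are well behaved).  The
other five population means recover to within ±0.1.  Per-agent recovery of
log b_pav correlates with the truth at r ≈ 0.8 at n = 300 — reliable for
rank-order inference, coarse for individual point estimates.

## Model comparison

- **ΔiBIC** plus per-subject ΔiL with a paired Wilcoxon signed-rank test
  (zero differences dropped, continuity correction).
- **Ppt** = exp(iL / n_trials): geometric-mean per-trial prediction
  probability; monotone in iL.
- **Protected exceedance probabilities**: variational Dirichlet
  random-effects scheme over per-subject log evidences; exceedance by
  Monte-Carlo over the Dirichlet posterior; protection via the Bayes
  omnibus risk, pxp = ep·(1 − bor) + bor/K.
- **Left-out likelihood (LOL)**: a seeded shuffle splits the cohort into a
  group-training set (default 300) and a test set.  Training yields each
  model's population prior.  Per test subject, emcee (affine-invariant
  ensemble, 16 walkers, 250 warmup + 750 kept steps, vectorized
  log-probability) samples the posterior over transformed parameters given
  the included trials only; held-out trials' realized actions and outcomes
  still drive value learning (informed handling) but contribute no
  likelihood, so the held-out data never inform parameter estimation.  The
  LOL is the log-mean-exp over posterior samples of the held-out trials'
  log-likelihood.  Walkers start from the subject's Laplace approximation.
  Convergence is checked with a split-R-hat that pools the ensemble per
  time segment (walkers of an ensemble sampler are not independent chains);
  subjects above 1.1 are excluded from the CI and logged.  The headline
  statistic is the median per-subject ΔPpt with a 10,000-resample bootstrap
  CI.

At study scale the per-trial advantage of the generative model over its
closest rival is of order 10⁻³, while the scaled-down run used in the test
suite (150 agents: 100 training / 50 test, two held-out trials) resolves
medians only to a few 10⁻³.  The suite therefore asserts that iBIC prefers
the generative model and that the LOL bootstrap CI does not lie entirely
below zero, rather than the sign of a point estimate the design cannot
resolve.

## The hidden-trial handling audit

Leaving trials out of a sequential learner's likelihood is subtle: the
value trajectory over included trials depends on what happened during the
left-out ones.  The audit simulates 10,000 epochs × 28 trials of a
two-armed bandit with deterministic returns (1 vs 5), hides the first 8
trials, and compares "informed" (realized hidden actions fill the gaps)
with "agnostic" (exact marginalization over all 2⁸ hidden action paths —
feasible because deterministic returns make the post-hidden state depend
only on per-action choice counts) on a 101-point learning-rate grid over
[0.005, 0.505], with a flat prior for the predictive p(h|v).  All three
grid likelihoods are validated against a brute-force path enumeration.

**Softmax scaling.**  The learner's "known softmax parameter τ = 0.1" is
implemented, by default, the way sensitivities enter the task models — as a
multiplicative exchange rate on the value scale (`value_scaling =
"exchange_rate"`, choice logits τ·ΔQ; the task models' softmax has no
temperature).  Under this reading the audit's principal findings hold: the
informed-minus-agnostic difference in hidden-trial predictive likelihood is
≈ −0.001 nats per 8 trials (≈ 0.01% of the per-trial prediction
probability), i.e. no practically relevant bias, and the η-greedy learner
shows none either.  The alternative temperature reading (logits ΔQ/τ,
available as `value_scaling="temperature"`) makes the learner essentially
deterministic after the first trials, saturates the 8-trial reference
estimates at the grid edge, and inflates every distance-based statistic by
an order of magnitude; we do not consider it a usable regime for this
audit.

Two structural facts the audit exposes are worth recording.  First, the
agnostic predictive p(h|v) is the coherent conditional of the joint model,
and the expected log score of a coherent conditional cannot be beaten
(Gibbs' inequality) — so the informed predictive is *always* very slightly
worse in expectation, and with 10,000 epochs even a 10⁻³-nat deficit is
many standard errors from zero.  "No bias" is a statement about practical
magnitude, not about exact equality, and the acceptance check that demands
|mean| < 3 SE is unattainable by construction.  Second, with deterministic
positive returns and a greedy policy that depends on values only through
the sign of their difference, gating exploratory updates on
better-than-expected returns (the "observation-violating" learner; our
gate: surprise relative to the best known value) provably cannot change
behaviour — the inferior action's value can never overtake the superior
one's — and a test asserts that its choice sequences are bit-identical to
the plain η-greedy learner's.  Any nonzero bias attributed to such a
learner must come from details beyond this setup (η defaults to 0.1 and is
configurable; ties are split by a fair coin).

The informed-vs-agnostic *ML-estimate closeness* statistic (mean paired
difference of |log distances| to the hidden-trial-only ML estimate) is
reported by the acceptance script; under the default scaling it is about
−0.05 log units at generative rate 0.15 (the agnostic estimate is slightly
closer), and it is sensitive to estimator and grid conventions — treat it
as descriptive, not as a decision criterion.

## Synthetic cohorts

Agents are drawn from independent Gaussians over transformed parameters.
The default valenced-learning population (transformed mean, SD):

| parameter | natural-space centre | transformed mean | SD |
|---|---|---|---|
| ρ | 6 | ln 6 ≈ 1.79 | 0.5 |
| λ_app, λ_av | 0.20 | logit 0.2 ≈ −1.39 | 0.8 |
| b_go | 0.7 | 0.7 | 0.7 |
| b_pav | 0.205 (median) | ln 0.205 ≈ −1.58 | 1.2 |
| ξ | 0.069 | logit 0.069 ≈ −2.60 | 0.5 |

These were calibrated once so that simulated cohorts reproduce the
behavioural anchors reported for this task in large community samples —
an early-trial G2AL−NG2W gap near 18 percentage points that closes to ≈ 0
late in the session, early NG2W performance slightly below chance, lapse
rates in the 5–10% band, a Pavlovian bias with natural-space median ≈ 0.2,
and per-trial predictability in the low-0.6 range — and then frozen.  The
b_pav SD of 1.2 spans biases from ≈ 0.02 to ≈ 2.5 across ±2 SD, the wide
individual variation this task is known for.  Wave-2 drift (optional)
adds to the transformed means only: ρ +0.3, λ +0.2 each, b_go −0.16,
b_pav −0.37, ξ −0.24 — the direction and rough magnitude of published
longitudinal change (bias, Go bias and lapses fall; sensitivity and
learning rates rise).  Robustness families replace the log-normal b_pav
marginal by a moment-matched gamma or natural-space normal (the latter
produces a small negative tail by construction).

What the generator does **not** emulate: within-person parameter stability
across waves (wave draws are independent, so synthetic retest correlations
of parameters are null by design — drift shifts distributions, not
individuals); attrition and missing responses; practice and fatigue within
a session; covariate structure (IQ/mood attachments are plain Gaussians for
plumbing only); and any misfit between brain and model — real humans are
noisier than their best-fitting agent, so recovery and reliability numbers
from this generator are upper bounds on what real data can give.

## Descriptive statistics

Early performance weights each condition's presentations 1..36 by
max(0, (19−k)/18) — a ramp anchored to within-condition position, reaching
0 at the condition's 19th presentation (the middle of its run); late is
presentations 19–36 unweighted.  The descriptive Pavlovian-bias index is
((G2W − NG2W) + (NG2AL − G2AL)) / 2 on overall accuracies.  Change and
cross-condition contrasts are medians of within-subject differences (not
differences of group medians — the two can disagree; the within-subject
median pairs naturally with the signed-rank test), with Bonferroni factors
of 4 (condition changes) and 8 (cross-condition family).

## Longitudinal psychometrics

- **Retest statistics**: Pearson r for approximately Gaussian measures
  (transformed ρ, b_go, iL), Spearman ρ for skewed ones (b_pav, λ, ξ) —
  overridable per measure; paired Wilcoxon change tests Bonferroni-corrected
  by the number of measures.
- **Gaussianization**: average ranks → ecdf with a 1/(n+1) boundary offset
  → inverse normal CDF → rescaled to the input's exact mean and SD.
  Rank-preserving, idempotent up to tolerance; constant vectors are
  rejected.
- **Latent change score model**: the just-identified univariate LCS is
  fitted by direct ML on the bivariate-normal parameterization (it is
  saturated, so ML = moment matching and the implied moments reproduce the
  sample moments exactly; an SEM backend would add a dependency without
  adding information).  Reported: change mean/variance, self-feedback β
  (β = −1 ⇔ x2 ⫫ x1, pure regression to the mean), residual variance,
  log-likelihood, BIC.  Nested comparisons by likelihood-ratio χ²:
  (a) β fixed at −1 (df 1, closed form); (b) equal mean and variance across
  waves with free covariance (df 2, Nelder-Mead on the exact bivariate
  likelihood).
- **Model-fit clustering**: full-covariance Gaussian mixtures over the
  joint (wave-1, wave-2) integrated likelihoods, K = 1..6, 20 restarts,
  covariance regularization 1e-6, K selected by BIC; hard assignments are
  argmax responsibilities.

## Problem sizes and determinism

The test suite runs the audit at 10,000 epochs, parameter recovery at
n = 300 agents, and the model-selection check at 150 agents (100 training /
50 test, reduced sampler settings); the property suite uses small n
throughout.  `scripts/acceptance.py` re-derives its two quantities at the
full audit size and n = 300.  Every stochastic component takes an explicit
seed; stage and subject seeds are derived through `SeedSequence` spawning,
so whole pipelines are reproducible end to end from one master seed.
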