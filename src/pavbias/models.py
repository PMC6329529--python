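"""Reinforcement-learning model family for the orthogonalized Go-NoGo task.

All models share the Rescorla-Wagner core: instrumental action values
Q(a, s) and Pavlovian stimulus values V(s) are updated after each responded
trial with learning rate lambda towards the scaled outcome rho * r,

    Q <- Q + lambda_v (rho_v r - Q),     V <- V + lambda_v (rho_v r - V),

where the ``v`` subscript marks parameters that may differ between win
(appetitive) and avoid-loss (aversive) trials.  Action propensities add a Go
bias and a Pavlovian bias coupling to V,

    q(go, s)   = Q(go, s) + b_go + b_pav V(s)
    q(nogo, s) = Q(nogo, s),

and choice probabilities are a lapse-contaminated softmax,

    p(a | s) = (1 - xi) softmax(q)(a) + xi / 2.

Model variants:

* ``valenced_learning``     - one rho, valence-specific learning rates.
* ``valenced_sensitivity``  - valence-specific rhos, one learning rate.
* ``sensitivity_ratio``     - reparameterizes valenced_sensitivity as an
  appetitive rho plus a log sensitivity ratio kappa = ln rho_av - ln rho_app;
  identical at the individual level, different population prior.
* each ``*_forget`` variant adds a retention fraction m: Q values of
  state-action pairs not experienced on a trial decay towards zero by
  factor m per trial (optionally V too).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task import GO, IS_WIN, MISSING, SessionData, TrialRecord

#: slot layout of the unified kernel parameter vector (natural space)
KERNEL_PARAMS = ("rho_app", "rho_av", "lam_app", "lam_av",
                 "b_go", "b_pav", "xi", "m")

_EPS = 1e-12


@dataclass(frozen=True)
class ModelSpec:
    """A named model variant: its parameters and their fitting transforms."""

    name: str
    base: str                  # valenced_learning | valenced_sensitivity | sensitivity_ratio
    params: tuple
    transforms: tuple          # per-parameter: log | logit | identity
    forgetting: bool = False

    @property
    def n_subject_params(self) -> int:
        return len(self.params)

    def __str__(self) -> str:
        return self.name


def _make_spec(base: str, forgetting: bool) -> ModelSpec:
    core = {
        "valenced_learning": (
            ("rho", "lam_app", "lam_av", "b_go", "b_pav", "xi"),
            ("log", "logit", "logit", "identity", "log", "logit"),
        ),
        "valenced_sensitivity": (
            ("rho_app", "rho_av", "lam", "b_go", "b_pav", "xi"),
            ("log", "log", "logit", "identity", "log", "logit"),
        ),
        "sensitivity_ratio": (
            ("rho_app", "kappa", "lam", "b_go", "b_pav", "xi"),
            ("log", "identity", "logit", "identity", "log", "logit"),
        ),
    }[base]
    params, transforms = core
    name = base
    if forgetting:
        params = params + ("m",)
        transforms = transforms + ("logit",)
        name = base + "_forget"
    return ModelSpec(name=name, base=base, params=params,
                     transforms=transforms, forgetting=forgetting)


MODELS = {}
for _base in ("valenced_learning", "valenced_sensitivity", "sensitivity_ratio"):
    for _forget in (False, True):
        _spec = _make_spec(_base, _forget)
        MODELS[_spec.name] = _spec


def get_model(name) -> ModelSpec:
    """Look up a model by name; ``"x+forget"`` is an alias for ``"x_forget"``."""
    if isinstance(name, ModelSpec):
        return name
    key = str(name).replace("+forget", "_forget")
    try:
        return MODELS[key]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(MODELS)}") from None


# ---------------------------------------------------------------------------
# parameter transforms


def _tf(value: float, transform: str, name: str) -> float:
    if transform == "identity":
        return float(value)
    if transform == "log":
        if value <= 0:
            raise ValueError(
                f"{name}={value} out of domain for log transform (must be > 0); "
                "clip away from 0 by machine epsilon if needed")
        return float(np.log(value))
    if transform == "logit":
        if not 0 < value < 1:
            raise ValueError(
                f"{name}={value} out of domain for logit transform (must be in "
                "(0, 1)); clip away from the boundary by machine epsilon")
        return float(np.log(value / (1.0 - value)))
    raise ValueError(f"unknown transform {transform!r}")


def _itf(value: float, transform: str) -> float:
    if transform == "identity":
        return float(value)
    if transform == "log":
        return float(np.exp(value))
    if transform == "logit":
        return float(1.0 / (1.0 + np.exp(-value)))
    raise ValueError(f"unknown transform {transform!r}")


def transform_params(params, model, direction: str = "to_transformed"):
    """Map between natural-space parameter dicts and transformed vectors.

    ``to_transformed``: dict -> ndarray in the model's parameter order.
    ``to_natural``: ndarray -> dict.  The two directions are inverse bijections.
    """
    model = get_model(model)
    if direction == "to_transformed":
        return np.array([_tf(params[p], tr, p)
                         for p, tr in zip(model.params, model.transforms)])
    if direction == "to_natural":
        vec = np.asarray(params, dtype=float)
        if vec.shape != (model.n_subject_params,):
            raise ValueError(f"expected vector of length {model.n_subject_params}")
        return {p: _itf(v, tr)
                for p, v, tr in zip(model.params, vec, model.transforms)}
    raise ValueError(f"unknown direction {direction!r}")


def to_kernel_params(params: dict, model) -> np.ndarray:
    """Expand a model-specific natural-space dict to the unified 8-slot layout."""
    model = get_model(model)
    p = np.empty(8)
    if model.base == "valenced_learning":
        p[0] = p[1] = params["rho"]
        p[2], p[3] = params["lam_app"], params["lam_av"]
    elif model.base == "valenced_sensitivity":
        p[0], p[1] = params["rho_app"], params["rho_av"]
        p[2] = p[3] = params["lam"]
    else:  # sensitivity_ratio
        p[0] = params["rho_app"]
        p[1] = params["rho_app"] * np.exp(params["kappa"])
        p[2] = p[3] = params["lam"]
    p[4], p[5], p[6] = params["b_go"], params["b_pav"], params["xi"]
    p[7] = params["m"] if model.forgetting else 1.0
    return p


def theta_to_kernel_params(theta, model) -> np.ndarray:
    """Transformed-space vector -> unified kernel parameter vector."""
    return to_kernel_params(transform_params(theta, model, "to_natural"), model)


# ---------------------------------------------------------------------------
# reference (plain Python) model mechanics


@dataclass
class LearnerState:
    """Q (4 stimuli x 2 actions, column 1 = Go) and V (4,) value arrays."""

    Q: np.ndarray
    V: np.ndarray

    @classmethod
    def zeros(cls) -> "LearnerState":
        return cls(Q=np.zeros((4, 2)), V=np.zeros(4))

    def copy(self) -> "LearnerState":
        return LearnerState(Q=self.Q.copy(), V=self.V.copy())


def _valenced(params: dict, model: ModelSpec, win: bool):
    """(rho, lam) applicable to a trial of the given valence."""
    p8 = to_kernel_params(params, model)
    return (p8[0], p8[2]) if win else (p8[1], p8[3])


def update_values(state: LearnerState, trial: TrialRecord, params: dict,
                  model) -> LearnerState:
    """One Rescorla-Wagner step; missing responses carry the state forward."""
    model = get_model(model)
    new = state.copy()
    if trial.action == "missing":
        return new
    s, a = trial.stimulus_id - 1, trial.action_code
    rho, lam = _valenced(params, model, trial.is_win)
    if model.forgetting:
        m = params["m"]
        for ss in range(4):
            for aa in range(2):
                if not (ss == s and aa == a):
                    new.Q[ss, aa] *= m
    target = rho * trial.outcome
    new.Q[s, a] += lam * (target - new.Q[s, a])
    new.V[s] += lam * (target - new.V[s])
    return new


def action_propensities(state: LearnerState, stimulus_id: int, params: dict):
    """(q_go, q_nogo) for a stimulus; biases apply to Go only."""
    s = stimulus_id - 1
    q_go = state.Q[s, 1] + params["b_go"] + params["b_pav"] * state.V[s]
    return float(q_go), float(state.Q[s, 0])


def choice_probability(q, xi: float):
    """Lapse-contaminated softmax over a (q_go, q_nogo) pair, overflow-safe."""
    if not 0 <= xi <= 1:
        raise ValueError(f"lapse rate xi must be in [0, 1], got {xi}")
    q = np.asarray(q, dtype=float)
    z = np.exp(q - q.max())
    p = (1.0 - xi) * z / z.sum() + xi / 2.0
    return float(p[0]), float(p[1])


def session_log_likelihood(session: SessionData, params: dict, model,
                           skip=frozenset()):
    """Sequential log-likelihood of a session's observed actions.

    Returns ``(total, per_trial)`` where ``per_trial`` holds the log
    probability of the observed action for every responded trial (NaN for
    missing responses) and ``total`` sums them over trials not in ``skip``
    (1-based indices).  Skipped trials' actions and outcomes still drive
    learning ("informed" handling) - they are merely excluded from the total.
    """
    model = get_model(model)
    skip = set(skip)
    state = LearnerState.zeros()
    per_trial = np.full(session.n_trials, np.nan)
    total = 0.0
    for rec in session.records():
        if rec.action == "missing":
            continue
        q = action_propensities(state, rec.stimulus_id, params)
        p_go, p_nogo = choice_probability(q, params["xi"])
        p_obs = p_go if rec.action_code == GO else p_nogo
        lp = np.log(max(p_obs, _EPS))
        per_trial[rec.trial_index - 1] = lp
        if rec.trial_index not in skip:
            total += lp
        state = update_values(state, rec, params, model)
    return total, per_trial


def simulated_accuracy(session: SessionData):
    """Fraction of correct responses per condition (missing excluded)."""
    from .task import CORRECT_ACTION

    out = np.full(4, np.nan)
    for c in range(4):
        mask = (session.condition == c) & (session.action != MISSING)
        if mask.any():
            out[c] = np.mean(session.action[mask] == CORRECT_ACTION[c])
    return out
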