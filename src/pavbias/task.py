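"""Orthogonalized Go-NoGo task structure and behavioural data containers.

The task presents four abstract stimuli, each tied to one of four conditions
crossing required action (Go / NoGo) with outcome valence (win / avoid-loss):
Go-to-Win (G2W), NoGo-to-Win (NG2W), Go-to-Avoid-Loss (G2AL) and
NoGo-to-Avoid-Loss (NG2AL).  A session comprises 144 trials (36 per stimulus,
fully randomized order).  The correct action yields the better of the two
possible outcomes with probability 0.8 (the feedback validity); win trials
pay +1 or 0, avoid-loss trials 0 or -1.
"""

from __future__ import annotations

import io
import zipfile
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CONDITIONS = ("G2W", "NG2W", "G2AL", "NG2AL")
CONDITION_CODE = {name: i for i, name in enumerate(CONDITIONS)}
SESSIONS = ("baseline", "short_followup", "long_followup")

GO, NOGO, MISSING = 1, 0, -1
ACTION_LABELS = {GO: "go", NOGO: "nogo", MISSING: "missing"}
ACTION_CODE = {v: k for k, v in ACTION_LABELS.items()}

N_TRIALS = 144
N_PER_CONDITION = 36
FEEDBACK_VALIDITY = 0.8

#: correct action per condition code (G2W, NG2W, G2AL, NG2AL)
CORRECT_ACTION = np.array([GO, NOGO, GO, NOGO])
#: True for win-valenced (appetitive) conditions
IS_WIN = np.array([True, True, False, False])

CSV_COLUMNS = [
    "participant_id",
    "session",
    "trial_index",
    "stimulus_id",
    "condition",
    "action",
    "outcome",
    "feedback_valid",
]


class CohortValidationError(ValueError):
    """A cohort or session violates the task invariants."""


@dataclass(frozen=True)
class TrialRecord:
    """One trial of one participant-session.

    ``stimulus_id`` is 1-based (1..4); ``condition`` is a label from
    :data:`CONDITIONS`; ``action`` one of ``go``/``nogo``/``missing``;
    ``outcome`` the realized monetary outcome in {-1, 0, +1}.
    """

    participant_id: str
    session: str
    trial_index: int
    stimulus_id: int
    condition: str
    action: str
    outcome: int
    feedback_valid: bool

    def __post_init__(self):
        if self.condition not in CONDITION_CODE:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.action not in ACTION_CODE:
            raise ValueError(f"unknown action {self.action!r}")
        win = IS_WIN[CONDITION_CODE[self.condition]]
        allowed = (0, 1) if win else (-1, 0)
        if self.action != "missing" and self.outcome not in allowed:
            raise ValueError(
                f"outcome {self.outcome} impossible in condition {self.condition}"
            )

    @property
    def condition_code(self) -> int:
        return CONDITION_CODE[self.condition]

    @property
    def action_code(self) -> int:
        return ACTION_CODE[self.action]

    @property
    def is_win(self) -> bool:
        return bool(IS_WIN[self.condition_code])

    @property
    def correct_action(self) -> int:
        return int(CORRECT_ACTION[self.condition_code])


@dataclass
class SessionData:
    """All trials of one participant in one wave, in presentation order.

    Trials are stored columnar for speed: integer arrays ``stimulus``
    (0-based), ``condition`` (codes into :data:`CONDITIONS`), ``action``
    (1 go, 0 nogo, -1 missing), ``outcome`` and boolean ``feedback_valid``.
    """

    participant_id: str
    session: str
    stimulus: np.ndarray
    condition: np.ndarray
    action: np.ndarray
    outcome: np.ndarray
    feedback_valid: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.condition)

    @property
    def trial_index(self) -> np.ndarray:
        """1-based, session-global trial indices."""
        return np.arange(1, self.n_trials + 1)

    def validate(self, n_trials: int = N_TRIALS) -> None:
        if self.n_trials != n_trials:
            raise CohortValidationError(
                f"participant {self.participant_id!r} session {self.session!r}: "
                f"{self.n_trials} trials, expected {n_trials}"
            )
        counts = np.bincount(self.condition, minlength=4)
        if not np.all(counts == n_trials // 4):
            raise CohortValidationError(
                f"participant {self.participant_id!r}: condition counts "
                f"{counts.tolist()} != {[n_trials // 4] * 4}"
            )
        responded = self.action != MISSING
        win = IS_WIN[self.condition]
        bad = responded & np.where(win, ~np.isin(self.outcome, (0, 1)),
                                   ~np.isin(self.outcome, (-1, 0)))
        if bad.any():
            t = int(np.flatnonzero(bad)[0]) + 1
            raise CohortValidationError(
                f"participant {self.participant_id!r}: impossible outcome at trial {t}"
            )

    def records(self):
        """Iterate trials as :class:`TrialRecord` objects."""
        for t in range(self.n_trials):
            yield TrialRecord(
                participant_id=self.participant_id,
                session=self.session,
                trial_index=t + 1,
                stimulus_id=int(self.stimulus[t]) + 1,
                condition=CONDITIONS[self.condition[t]],
                action=ACTION_LABELS[int(self.action[t])],
                outcome=int(self.outcome[t]),
                feedback_valid=bool(self.feedback_valid[t]),
            )


@dataclass
class Cohort:
    """One wave of data: one :class:`SessionData` per participant."""

    sessions: list
    wave: str = "baseline"

    def __len__(self) -> int:
        return len(self.sessions)

    def __iter__(self):
        return iter(self.sessions)

    @property
    def participant_ids(self) -> list:
        return [s.participant_id for s in self.sessions]

    def validate(self, n_trials: int = N_TRIALS) -> None:
        ids = self.participant_ids
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate participant ids: {dupes}")
        for s in self.sessions:
            s.validate(n_trials=n_trials)

    def subset(self, participant_ids) -> "Cohort":
        wanted = set(participant_ids)
        return Cohort(
            sessions=[s for s in self.sessions if s.participant_id in wanted],
            wave=self.wave,
        )


@dataclass
class TaskSchedule:
    """Pre-drawn trial order and feedback-validity draws for one session.

    ``validity_draw[t]`` True means the designed contingency holds on trial t
    (correct action -> better outcome); with probability 1 - feedback_validity
    the mapping is inverted.
    """

    stimulus: np.ndarray      # 0-based stimulus index, == condition code
    condition: np.ndarray     # condition codes
    validity_draw: np.ndarray
    feedback_validity: float = FEEDBACK_VALIDITY

    def __len__(self) -> int:
        return len(self.condition)


def make_task_schedule(seed: int, n_per_condition: int = N_PER_CONDITION,
                       feedback_validity: float = FEEDBACK_VALIDITY) -> TaskSchedule:
    """Uniformly random interleaving of 4 x ``n_per_condition`` trials.

    Each stimulus is shown exactly ``n_per_condition`` times; per-trial
    validity draws are Bernoulli(``feedback_validity``).  Deterministic
    given ``seed``.
    """
    if n_per_condition < 1:
        raise ValueError(f"n_per_condition must be >= 1, got {n_per_condition}")
    rng = np.random.default_rng(seed)
    condition = rng.permutation(np.repeat(np.arange(4), n_per_condition))
    validity = rng.random(condition.size) < feedback_validity
    return TaskSchedule(
        stimulus=condition.copy(),
        condition=condition,
        validity_draw=validity,
        feedback_validity=feedback_validity,
    )


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Long-format DataFrame, one row per trial."""
    parts = []
    for s in cohort.sessions:
        parts.append(pd.DataFrame({
            "participant_id": s.participant_id,
            "session": s.session,
            "trial_index": s.trial_index,
            "stimulus_id": s.stimulus + 1,
            "condition": np.asarray(CONDITIONS)[s.condition],
            "action": [ACTION_LABELS[int(a)] for a in s.action],
            "outcome": s.outcome,
            "feedback_valid": s.feedback_valid,
        }))
    if not parts:
        return pd.DataFrame(columns=CSV_COLUMNS)
    return pd.concat(parts, ignore_index=True)[CSV_COLUMNS]


def frame_to_cohort(frame: pd.DataFrame, wave: str = "baseline",
                    validate: bool = True, n_trials: int = N_TRIALS) -> Cohort:
    missing_cols = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise CohortValidationError(f"missing columns: {missing_cols}")
    bad_cond = ~frame["condition"].isin(CONDITIONS)
    if bad_cond.any():
        row = int(frame.index[bad_cond][0])
        raise CohortValidationError(f"row {row}: unknown condition "
                                    f"{frame.loc[row, 'condition']!r}")
    bad_act = ~frame["action"].isin(ACTION_CODE)
    if bad_act.any():
        row = int(frame.index[bad_act][0])
        raise CohortValidationError(f"row {row}: unknown action "
                                    f"{frame.loc[row, 'action']!r}")
    sessions = []
    for pid, g in frame.groupby("participant_id", sort=False):
        g = g.sort_values("trial_index")
        sessions.append(SessionData(
            participant_id=str(pid),
            session=str(g["session"].iloc[0]),
            stimulus=g["stimulus_id"].to_numpy(dtype=np.int64) - 1,
            condition=np.array([CONDITION_CODE[c] for c in g["condition"]]),
            action=np.array([ACTION_CODE[a] for a in g["action"]]),
            outcome=g["outcome"].to_numpy(dtype=np.int64),
            feedback_valid=g["feedback_valid"].astype(bool).to_numpy(),
        ))
    cohort = Cohort(sessions=sessions, wave=wave)
    if validate:
        cohort.validate(n_trials=n_trials)
    return cohort


def write_cohort(cohort: Cohort, path, format: str = "long_csv") -> None:
    """Write a cohort as canonical long CSV (one row per trial)."""
    if format != "long_csv":
        raise ValueError(f"unsupported write format {format!r}")
    cohort_to_frame(cohort).to_csv(path, index=False)


#: Default mapping from per-subject MAT-file arrays onto trial fields.
#: Values are the MAT variable names; adjust to the layout of the container
#: actually in hand (the deposited files' internal layout is configurable).
DEFAULT_MAT_FIELD_MAP = {
    "stimulus": "stim",       # 1-based stimulus / condition index per trial
    "action": "action",       # 1 = go, 0 = nogo, negative/NaN = missing
    "outcome": "outcome",     # realized outcome per trial
}


def load_cohort(path, format: str = "long_csv", wave: str = "baseline",
                field_map: dict | None = None, validate: bool = True,
                n_trials: int = N_TRIALS) -> Cohort:
    """Read behavioural data into a validated :class:`Cohort`.

    ``long_csv`` is the canonical format (columns :data:`CSV_COLUMNS`).
    ``matfile`` reads a ZIP of MAT v5 files, one per participant, mapping
    arrays onto trial fields via ``field_map``.
    """
    if format == "long_csv":
        try:
            frame = pd.read_csv(path)
        except pd.errors.ParserError as exc:
            raise CohortValidationError(f"malformed CSV {path}: {exc}") from exc
        return frame_to_cohort(frame, wave=wave, validate=validate,
                               n_trials=n_trials)
    if format == "matfile":
        return _load_mat_zip(path, wave=wave,
                             field_map=field_map or DEFAULT_MAT_FIELD_MAP,
                             validate=validate, n_trials=n_trials)
    raise ValueError(f"unsupported format {format!r}")


def _load_mat_zip(path, wave, field_map, validate, n_trials):
    from scipy.io import loadmat

    sessions = []
    with zipfile.ZipFile(path) as zf:
        names = sorted(n for n in zf.namelist() if n.lower().endswith(".mat"))
        if not names:
            raise CohortValidationError(f"{path}: no .mat members found")
        for name in names:
            mat = loadmat(io.BytesIO(zf.read(name)), squeeze_me=True)
            try:
                stim = np.asarray(mat[field_map["stimulus"]]).ravel()
                act = np.asarray(mat[field_map["action"]], dtype=float).ravel()
                out = np.asarray(mat[field_map["outcome"]], dtype=float).ravel()
            except KeyError as exc:
                raise CohortValidationError(
                    f"{name}: MAT variable {exc} not found; adjust field_map"
                ) from exc
            action = np.where(np.isnan(act) | (act < 0), MISSING,
                              act.astype(np.int64))
            condition = stim.astype(np.int64) - 1
            sessions.append(SessionData(
                participant_id=name.rsplit("/", 1)[-1].rsplit(".", 1)[0],
                session=wave,
                stimulus=condition.copy(),
                condition=condition,
                action=action,
                outcome=np.nan_to_num(out).astype(np.int64),
                feedback_valid=np.ones(len(condition), dtype=bool),
            ))
    cohort = Cohort(sessions=sessions, wave=wave)
    if validate:
        cohort.validate(n_trials=n_trials)
    return cohort
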