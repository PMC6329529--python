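"""Model-free performance summaries and paired condition tests.

Performance is the fraction of correct responses per condition (the correct
action is Go in G2W/G2AL, NoGo in NG2W/NG2AL), with missing responses
excluded from numerator and denominator.  "Early" performance weights each
condition's trials by a ramp decreasing linearly from 1 at the condition's
first presentation to 0 at its 19th (the middle of the 36); "late" uses
presentations 19-36 unweighted.

The descriptive Pavlovian-bias index is the congruency interaction
((G2W - NG2W) + (NG2AL - G2AL)) / 2: positive when Pavlovian-congruent
conditions are performed better than incongruent ones.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .task import CONDITIONS, CORRECT_ACTION, MISSING, Cohort, SessionData

PHASES = ("early", "late", "all")


def _phase_weights(n: int, phase: str) -> np.ndarray:
    k = np.arange(1, n + 1)
    if phase == "early":
        mid = n // 2 + 1
        return np.maximum(0.0, (mid - k) / (mid - 1))
    if phase == "late":
        return (k > n // 2).astype(float)
    if phase == "all":
        return np.ones(n)
    raise ValueError(f"unknown phase {phase!r}; one of {PHASES}")


def weighted_performance(session: SessionData, phase: str = "all") -> np.ndarray:
    """Per-condition (weighted) fraction correct; NaN if a condition has no
    responded trials in the phase window."""
    out = np.full(4, np.nan)
    for c in range(4):
        idx = np.flatnonzero(session.condition == c)
        w = _phase_weights(idx.size, phase)
        responded = session.action[idx] != MISSING
        w = w * responded
        if w.sum() <= 0:
            continue
        correct = (session.action[idx] == CORRECT_ACTION[c]).astype(float)
        out[c] = float(np.sum(w * correct) / np.sum(w))
    return out


def pav_bias_index(fractions) -> float:
    """((G2W - NG2W) + (NG2AL - G2AL)) / 2; NaN if any condition undefined."""
    f = np.asarray(fractions, dtype=float)
    if f.shape != (4,):
        raise ValueError("expected the four per-condition fractions")
    return float(((f[0] - f[1]) + (f[3] - f[2])) / 2.0)


def performance_summary(cohort: Cohort) -> pd.DataFrame:
    """Per-participant table of per-condition fractions for all phases plus
    the descriptive Pavlovian-bias index (computed on overall fractions)."""
    rows = []
    for s in cohort:
        row = {"participant_id": s.participant_id, "session": s.session}
        for phase in PHASES:
            f = weighted_performance(s, phase)
            for c, name in enumerate(CONDITIONS):
                row[f"{phase}_{name}"] = f[c]
            row[f"{phase}_pav_index"] = pav_bias_index(f)
        rows.append(row)
    return pd.DataFrame(rows).set_index("participant_id")


def _paired_wilcoxon(diff: np.ndarray):
    diff = diff[np.isfinite(diff)]
    if diff.size == 0:
        return np.nan, np.nan
    if np.allclose(diff, 0):
        return 0.0, 1.0
    stat, p = wilcoxon(diff, zero_method="wilcox", correction=True)
    return float(np.median(diff)), float(p)


def condition_change_tests(cohort_a: Cohort, cohort_b: Cohort,
                           phase: str = "all") -> pd.DataFrame:
    """Per-condition paired change (wave B minus wave A) for participants in
    both waves: median within-subject difference, Wilcoxon p, and Bonferroni
    correction for the 4 conditions."""
    ids = sorted(set(cohort_a.participant_ids) & set(cohort_b.participant_ids))
    if len(ids) < 10:
        raise ValueError(f"need >= 10 matched participants, got {len(ids)}")
    by_a = {s.participant_id: s for s in cohort_a}
    by_b = {s.participant_id: s for s in cohort_b}
    fa = np.array([weighted_performance(by_a[i], phase) for i in ids])
    fb = np.array([weighted_performance(by_b[i], phase) for i in ids])
    rows = []
    for c, name in enumerate(CONDITIONS):
        med, p = _paired_wilcoxon(fb[:, c] - fa[:, c])
        rows.append({"condition": name, "median_diff": med, "p": p,
                     "p_bonferroni": min(1.0, 4 * p) if np.isfinite(p) else np.nan})
    return pd.DataFrame(rows).set_index("condition")


def cross_condition_tests(cohort: Cohort, phase: str = "early") -> pd.DataFrame:
    """All pairwise within-subject condition contrasts for one phase:
    median difference, Wilcoxon p, Bonferroni x8 (the phase-pair family)."""
    f = np.array([weighted_performance(s, phase) for s in cohort])
    rows = []
    for c1, c2 in itertools.combinations(range(4), 2):
        med, p = _paired_wilcoxon(f[:, c1] - f[:, c2])
        rows.append({
            "pair": f"{CONDITIONS[c1]}-{CONDITIONS[c2]}",
            "median_diff": med, "p": p,
            "p_bonferroni": min(1.0, 8 * p) if np.isfinite(p) else np.nan,
        })
    return pd.DataFrame(rows).set_index("pair")
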