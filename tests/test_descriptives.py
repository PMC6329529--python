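import numpy as np
import pytest

from conftest import make_scripted_session
from pavbias.descriptives import (condition_change_tests,
                                  cross_condition_tests, pav_bias_index,
                                  performance_summary, weighted_performance)
from pavbias.task import Cohort, SessionData, make_task_schedule
from pavbias.simulate import simulate_session


def _session_with_pattern(correct_early, correct_late, seed=0):
    """All conditions share the same early/late correctness pattern."""
    sched = make_task_schedule(seed)
    pos = np.zeros(144, dtype=int)
    seen = {c: 0 for c in range(4)}
    for t, c in enumerate(sched.condition):
        seen[c] += 1
        pos[t] = seen[c]
    from pavbias.task import CORRECT_ACTION

    right = CORRECT_ACTION[sched.condition]
    correct = np.where(pos <= 18, correct_early, correct_late)
    action = np.where(correct, right, 1 - right)
    win = sched.condition < 2
    outcome = np.where(win, 1, -1)
    outcome = np.where(action == right, np.where(win, 1, 0), outcome)
    return SessionData(participant_id="p", session="baseline",
                       stimulus=sched.stimulus.copy(),
                       condition=sched.condition.copy(),
                       action=action.astype(np.int64),
                       outcome=outcome.astype(np.int64),
                       feedback_valid=np.ones(144, dtype=bool))


class TestWeightedPerformance:
    def test_all_correct_and_all_incorrect(self):
        for flag, want in ((True, 1.0), (False, 0.0)):
            s = _session_with_pattern(flag, flag)
            for phase in ("early", "late", "all"):
                assert np.allclose(weighted_performance(s, phase), want)

    def test_half_split_matches_ramp_definition(self):
        s = _session_with_pattern(True, False)
        assert np.allclose(weighted_performance(s, "early"), 1.0)
        assert np.allclose(weighted_performance(s, "late"), 0.0)
        assert np.allclose(weighted_performance(s, "all"), 0.5)

    def test_missing_responses_excluded_from_denominator(self):
        s = _session_with_pattern(True, True)
        g2w = np.flatnonzero(s.condition == 0)
        s.action[g2w[:10]] = -1
        f = weighted_performance(s, "all")
        assert f[0] == 1.0   # remaining responses all correct
        s.action[g2w] = -1
        f = weighted_performance(s, "all")
        assert np.isnan(f[0]) and np.isfinite(f[1:]).all()

    def test_invariant_to_other_conditions_reordering(self, vl_session):
        base = weighted_performance(vl_session, "early")[0]
        other = np.flatnonzero(vl_session.condition != 0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(other)
        s2 = SessionData(
            participant_id="p", session="baseline",
            stimulus=vl_session.stimulus.copy(),
            condition=vl_session.condition.copy(),
            action=vl_session.action.copy(),
            outcome=vl_session.outcome.copy(),
            feedback_valid=vl_session.feedback_valid.copy())
        for arr in (s2.stimulus, s2.condition, s2.action, s2.outcome):
            arr[other] = arr[perm]
        assert weighted_performance(s2, "early")[0] == pytest.approx(base)


class TestPavBiasIndex:
    def test_equal_conditions_give_zero(self):
        assert pav_bias_index([0.7, 0.7, 0.7, 0.7]) == 0.0

    def test_hand_arithmetic(self):
        # ((0.9 - 0.5) + (0.8 - 0.6)) / 2 = 0.3
        assert pav_bias_index([0.9, 0.5, 0.6, 0.8]) == pytest.approx(0.3)

    def test_antisymmetric_under_congruency_swap(self):
        f = np.array([0.9, 0.5, 0.6, 0.8])
        swapped = f[[1, 0, 3, 2]]     # swap within each valence
        assert pav_bias_index(swapped) == pytest.approx(-pav_bias_index(f))

    def test_nan_propagates(self):
        assert np.isnan(pav_bias_index([np.nan, 0.5, 0.6, 0.8]))


class TestChangeTests:
    def _cohort(self, rates, n, wave, seed0):
        return Cohort(wave=wave, sessions=[
            make_scripted_session(f"P{i}", rates, seed=seed0 + i,
                                  session=wave) for i in range(n)])

    def test_identical_cohorts_are_null(self):
        a = self._cohort([0.8, 0.5, 0.6, 0.7], 15, "baseline", 0)
        res = condition_change_tests(a, a)
        assert np.allclose(res["median_diff"], 0.0)
        assert np.allclose(res["p_bonferroni"], 1.0)

    def test_planted_g2al_improvement_detected(self):
        a = self._cohort([0.8, 0.5, 0.60, 0.7], 300, "baseline", 0)
        b = self._cohort([0.8, 0.5, 0.65, 0.7], 300, "long_followup", 0)
        res = condition_change_tests(a, b)
        assert res.loc["G2AL", "median_diff"] == pytest.approx(0.05, abs=0.02)
        assert res.loc["G2AL", "p_bonferroni"] < 0.05
        assert abs(res.loc["G2W", "median_diff"]) < 0.02

    def test_requires_matched_participants(self):
        a = self._cohort([0.8, 0.5, 0.6, 0.7], 12, "baseline", 0)
        b = Cohort(wave="w2", sessions=[
            make_scripted_session(f"Q{i}", [0.8, 0.5, 0.6, 0.7], seed=i)
            for i in range(12)])
        with pytest.raises(ValueError):
            condition_change_tests(a, b)


class TestCrossConditionTests:
    def test_chance_performers_show_no_contrasts(self):
        agent = {"rho": 1.0, "lam_app": 0.2, "lam_av": 0.2, "b_go": 0.0,
                 "b_pav": 0.1, "xi": 1.0}
        cohort = Cohort(sessions=[
            simulate_session(agent, "valenced_learning",
                             make_task_schedule(i), seed=i,
                             participant_id=f"C{i}") for i in range(40)])
        res = cross_condition_tests(cohort, phase="early")
        assert np.all(np.abs(res["median_diff"]) < 0.2)
        assert np.all(res["p_bonferroni"] > 0.01)

    def test_planted_incongruent_gap(self):
        cohort = Cohort(sessions=[
            make_scripted_session(f"P{i}", [0.85, 0.45, 0.63, 0.75], seed=i)
            for i in range(120)])
        res = cross_condition_tests(cohort, phase="early")
        gap = res.loc["NG2W-G2AL", "median_diff"]
        assert gap == pytest.approx(-0.18, abs=0.05)
        assert res.loc["NG2W-G2AL", "p_bonferroni"] < 1e-5


def test_performance_summary_table(small_cohort):
    cohort, _ = small_cohort
    table = performance_summary(cohort)
    assert len(table) == len(cohort)
    assert "early_G2W" in table.columns and "all_pav_index" in table.columns
    frac_cols = [c for c in table.columns
                 if c.endswith(tuple(["G2W", "NG2W", "G2AL", "NG2AL"]))]
    vals = table[frac_cols].to_numpy()
    assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 1
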