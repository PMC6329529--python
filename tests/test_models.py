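import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pavbias.models import (LearnerState, MODELS, action_propensities,
                            choice_probability, get_model,
                            session_log_likelihood, transform_params,
                            update_values)
from pavbias.emfit import session_nll_batch
from pavbias.task import SessionData, TrialRecord, make_task_schedule
from pavbias.simulate import PopulationSpec, sample_population, simulate_session


def _trial(action="go", outcome=1, condition="G2W", stimulus_id=1, idx=1):
    return TrialRecord(participant_id="p", session="baseline",
                       trial_index=idx, stimulus_id=stimulus_id,
                       condition=condition, action=action, outcome=outcome,
                       feedback_valid=True)


PARAMS = {"rho": 2.0, "lam_app": 0.1, "lam_av": 0.2, "b_go": 0.2,
          "b_pav": 0.5, "xi": 0.1}


class TestUpdateValues:
    def test_zero_learning_rate_freezes_state(self):
        state = LearnerState.zeros()
        state.Q += 0.3
        p = dict(PARAMS, lam_app=0.0)
        new = update_values(state, _trial(), p, "valenced_learning")
        assert np.array_equal(new.Q, state.Q)
        assert np.array_equal(new.V, state.V)

    def test_hand_evaluated_delta_rule(self):
        # Q=0, lam=0.1, rho=2, r=+1  ->  Q' = 0 + 0.1 * (2*1 - 0) = 0.2
        new = update_values(LearnerState.zeros(), _trial(), PARAMS,
                            "valenced_learning")
        assert new.Q[0, 1] == pytest.approx(0.2, abs=1e-12)
        assert new.V[0] == pytest.approx(0.2, abs=1e-12)

    def test_unshown_stimuli_carried_forward(self):
        state = LearnerState.zeros()
        state.Q[:] = 0.4
        state.V[:] = -0.2
        new = update_values(state, _trial(stimulus_id=2, condition="NG2W"),
                            PARAMS, "valenced_learning")
        untouched = [0, 2, 3]
        assert np.array_equal(new.Q[untouched], state.Q[untouched])
        assert np.array_equal(new.V[untouched], state.V[untouched])

    def test_missing_response_is_noop(self):
        state = LearnerState.zeros()
        state.Q[:] = 1.0
        new = update_values(state, _trial(action="missing"), PARAMS,
                            "valenced_learning")
        assert np.array_equal(new.Q, state.Q)

    def test_aversive_trials_use_aversive_rate(self):
        new = update_values(LearnerState.zeros(),
                            _trial(condition="G2AL", outcome=-1), PARAMS,
                            "valenced_learning")
        # lam_av=0.2, rho=2, r=-1 -> -0.4
        assert new.Q[0, 1] == pytest.approx(-0.4, abs=1e-12)

    def test_v_updates_even_on_nogo(self):
        new = update_values(LearnerState.zeros(),
                            _trial(action="nogo", outcome=1), PARAMS,
                            "valenced_learning")
        assert new.V[0] == pytest.approx(0.2, abs=1e-12)
        assert new.Q[0, 1] == 0.0  # go value untouched

    def test_forgetting_decays_unexperienced_pairs_only(self):
        state = LearnerState.zeros()
        state.Q[:] = 1.0
        p = dict(PARAMS, m=0.9)
        new = update_values(state, _trial(), p, "valenced_learning_forget")
        assert new.Q[1, 0] == pytest.approx(0.9)
        # realized pair: RW update from its pre-decay value
        assert new.Q[0, 1] == pytest.approx(1.0 + 0.1 * (2.0 - 1.0))


class TestPropensitiesAndChoice:
    def test_zero_biases_reduce_to_q(self):
        state = LearnerState.zeros()
        state.Q[0] = [0.3, 0.7]
        q = action_propensities(state, 1, dict(PARAMS, b_go=0.0, b_pav=0.0))
        assert q == (0.7, 0.3)

    def test_hand_arithmetic(self):
        state = LearnerState.zeros()
        state.Q[0, 1] = 0.5
        state.V[0] = -0.4
        q_go, _ = action_propensities(state, 1,
                                      dict(PARAMS, b_go=0.2, b_pav=0.3))
        assert q_go == pytest.approx(0.58)

    def test_nogo_propensity_never_biased(self):
        state = LearnerState.zeros()
        state.Q[2] = [0.9, 0.1]
        state.V[2] = 5.0
        _, q_ng = action_propensities(state, 3, PARAMS)
        assert q_ng == 0.9

    def test_pure_lapse_is_uniform(self):
        assert choice_probability((5.0, -3.0), 1.0) == (0.5, 0.5)

    def test_equal_propensities_symmetric(self):
        assert choice_probability((0.7, 0.7), 0.0) == (0.5, 0.5)

    def test_closed_form_logistic(self):
        p_go, _ = choice_probability((1.0, 0.0), 0.0)
        assert p_go == pytest.approx(0.7311, abs=5e-5)
        p_go, _ = choice_probability((1.0, 0.0), 0.1)
        assert p_go == pytest.approx(0.7080, abs=5e-5)

    def test_overflow_safe(self):
        p_go, p_ng = choice_probability((800.0, -800.0), 0.2)
        assert p_go == pytest.approx(0.9)
        assert p_ng == pytest.approx(0.1)

    @given(st.floats(-30, 30), st.floats(-30, 30),
           st.floats(0, 1).filter(lambda x: 0 <= x <= 1))
    def test_probabilities_sum_to_one_within_lapse_band(self, qg, qn, xi):
        p_go, p_ng = choice_probability((qg, qn), xi)
        assert p_go + p_ng == pytest.approx(1.0, abs=1e-12)
        assert xi / 2 - 1e-12 <= p_go <= 1 - xi / 2 + 1e-12


class TestSessionLikelihood:
    def test_lapse_only_is_chance(self, vl_session):
        total, per = session_log_likelihood(vl_session, dict(PARAMS, xi=1.0),
                                            "valenced_learning")
        assert total == pytest.approx(144 * np.log(0.5), abs=1e-9)
        assert np.allclose(per, np.log(0.5))

    def test_two_trial_hand_worked_oracle(self):
        session = SessionData(
            participant_id="p", session="baseline",
            stimulus=np.array([0, 0]), condition=np.array([0, 0]),
            action=np.array([1, 0]), outcome=np.array([1, 0]),
            feedback_valid=np.array([True, True]))
        total, per = session_log_likelihood(session, PARAMS,
                                            "valenced_learning")
        # trial 1: q_go = b_go = 0.2, q_ng = 0
        p1 = 0.9 * np.exp(0.2) / (np.exp(0.2) + 1.0) + 0.05
        # update: Q(go) = V = 0.1 * (2*1) = 0.2
        # trial 2: q_go = 0.2 + 0.2 + 0.5*0.2 = 0.5; nogo chosen
        p2 = 1.0 - (0.9 * np.exp(0.5) / (np.exp(0.5) + 1.0) + 0.05)
        assert total == pytest.approx(np.log(p1) + np.log(p2), abs=1e-12)
        assert per[0] == pytest.approx(np.log(p1), abs=1e-12)

    def test_skip_additivity(self, vl_session, vl_agent):
        full, per = session_log_likelihood(vl_session, vl_agent,
                                           "valenced_learning")
        skipped, _ = session_log_likelihood(vl_session, vl_agent,
                                            "valenced_learning",
                                            skip={48, 96})
        assert skipped == pytest.approx(full - per[47] - per[95], abs=1e-10)

    @pytest.mark.parametrize("model", ["valenced_learning",
                                       "valenced_sensitivity",
                                       "valenced_learning_forget"])
    def test_fast_kernel_matches_reference(self, model, small_cohort):
        """Dual route: the compiled kernel must agree with the plain-Python
        reference on random sessions, including missing responses."""
        cohort, _ = small_cohort
        spec = get_model(model)
        rng = np.random.default_rng(3)
        for session in cohort.sessions[:5]:
            session = SessionData(**{**session.__dict__})
            session.action = session.action.copy()
            session.action[rng.integers(0, 144, 5)] = -1
            draws = rng.normal(0, 0.8, spec.n_subject_params)
            nat = transform_params(draws, spec, "to_natural")
            ref, _ = session_log_likelihood(session, nat, spec)
            fast = -session_nll_batch(draws, session, spec)[0]
            assert fast == pytest.approx(ref, abs=1e-9)

    def test_valenced_sensitivity_equals_sensitivity_ratio(self, vl_session):
        vs = {"rho_app": 3.0, "rho_av": 5.0, "lam": 0.2, "b_go": 0.4,
              "b_pav": 0.3, "xi": 0.05}
        sr = {"rho_app": 3.0, "kappa": np.log(5.0) - np.log(3.0),
              "lam": 0.2, "b_go": 0.4, "b_pav": 0.3, "xi": 0.05}
        l1, _ = session_log_likelihood(vl_session, vs, "valenced_sensitivity")
        l2, _ = session_log_likelihood(vl_session, sr, "sensitivity_ratio")
        assert l1 == pytest.approx(l2, abs=1e-10)


class TestTransforms:
    @given(st.lists(st.floats(-4, 4), min_size=6, max_size=6))
    def test_round_trip_bijection(self, vec):
        model = get_model("valenced_learning")
        nat = transform_params(np.array(vec), model, "to_natural")
        back = transform_params(nat, model, "to_transformed")
        assert np.allclose(back, vec, atol=1e-10)

    def test_unit_pavlovian_bias_maps_to_zero(self):
        t = transform_params(dict(PARAMS, b_pav=1.0), "valenced_learning")
        assert t[4] == 0.0

    def test_boundary_values_raise_with_guidance(self):
        with pytest.raises(ValueError, match="epsilon"):
            transform_params(dict(PARAMS, lam_app=1.0), "valenced_learning")
        with pytest.raises(ValueError, match="epsilon"):
            transform_params(dict(PARAMS, b_pav=0.0), "valenced_learning")

    def test_lognormal_prior_median_is_exp_mu(self):
        spec = PopulationSpec(n=4001, seed=3)
        agents = sample_population(spec)[0]
        bpav = np.array([a["b_pav"] for a in agents])
        assert np.median(np.log(bpav)) == pytest.approx(
            spec.mean["b_pav"], abs=3 * 1.2 * 1.2533 / np.sqrt(4001))

    def test_model_registry_aliases(self):
        assert get_model("valenced_learning+forget").forgetting
        assert len(MODELS) == 6
        with pytest.raises(KeyError):
            get_model("nope")
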