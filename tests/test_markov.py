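"""Markov engine: matrix construction, cohort iteration, event accounting."""
import numpy as np
import pytest

from ccta_cea import (
    EffectInputs,
    HealthState,
    InvalidRateError,
    ModelConfig,
    NumericError,
    Stratum,
    TransitionMatrix,
    TreatmentState,
    build_transition_matrix,
    expected_events,
    microsimulate,
    run_cohort,
)
from ccta_cea.markov import trace_to_frame

S_NO = Stratum.parse("non_obstructive:high")
S_OB = Stratum.parse("obstructive:high")
NO_TREAT = TreatmentState(0, 0)


def _single_state_matrix():
    return TransitionMatrix((HealthState.NO_OBSTRUCTIVE_CAD,), np.array([[1.0]]))


def _two_state_matrix(p_die):
    return TransitionMatrix(
        (HealthState.NO_OBSTRUCTIVE_CAD, HealthState.OTHER_DEATH),
        np.array([[1.0 - p_die, p_die], [0.0, 1.0]]),
    )


class TestBuildTransitionMatrix:
    def test_no_treatment_change_reproduces_baseline(self, params):
        effects = EffectInputs.from_parameters(params)
        matrix = build_transition_matrix(S_NO, params, NO_TREAT, effects)
        row = params.transition_probs[S_NO]["no_obstructive_cad"]
        i = matrix.index(HealthState.NO_OBSTRUCTIVE_CAD)
        for to, p in row.items():
            assert matrix.probs[i, matrix.index(HealthState(to))] == p

    def test_obstructive_stratum_drops_disease_free_state(self, params):
        effects = EffectInputs.from_parameters(params)
        matrix = build_transition_matrix(S_OB, params, NO_TREAT, effects)
        assert HealthState.NO_OBSTRUCTIVE_CAD not in matrix.states
        assert len(matrix.states) == 6

    def test_uniform_rr_halves_events_and_stay_absorbs(self, params):
        # baseline LDL chosen so initiation lowers LDL by exactly 1 mmol/L,
        # making every MACE relative risk equal rr_per_mmol = 0.5
        effects = EffectInputs(
            baseline_ldl_mmol=1.0 / 0.48,
            rr_per_mmol={k: 0.5 for k in params.rr_per_mmol},
        )
        base = build_transition_matrix(S_NO, params, NO_TREAT, effects)
        treated = build_transition_matrix(S_NO, params, TreatmentState(0, 40), effects)
        i = base.index(HealthState.NO_OBSTRUCTIVE_CAD)
        removed = 0.0
        for event in ("mi", "stroke", "heart_failure", "cardiac_death"):
            j = base.index(HealthState(event))
            assert treated.probs[i, j] == pytest.approx(0.5 * base.probs[i, j])
            removed += 0.5 * base.probs[i, j]
        assert treated.probs[i, i] == pytest.approx(base.probs[i, i] + removed)
        assert treated.probs[i].sum() == pytest.approx(1.0, abs=1e-12)

    def test_overfull_row_raises_named_error(self, params):
        params.transition_probs[S_NO]["mi"]["stroke"] = 0.999
        effects = EffectInputs.from_parameters(params)
        with pytest.raises(InvalidRateError, match="mi"):
            build_transition_matrix(S_NO, params, NO_TREAT, effects)

    def test_death_rows_are_absorbing(self, params):
        effects = EffectInputs.from_parameters(params)
        matrix = build_transition_matrix(S_NO, params, NO_TREAT, effects)
        for state in (HealthState.CARDIAC_DEATH, HealthState.OTHER_DEATH):
            i = matrix.index(state)
            expected = np.zeros(len(matrix.states))
            expected[i] = 1.0
            assert np.array_equal(matrix.probs[i], expected)


class TestRunCohort:
    def test_identity_matrix_full_utility_gives_horizon_qalys(self, config, params):
        params.utility["no_obstructive_cad"] = 1.0
        config.discount_rate_annual = 0.0
        trace = run_cohort(_single_state_matrix(), [1.0], config, params, NO_TREAT)
        assert trace.discounted_qaly == pytest.approx(30.0)
        assert trace.undiscounted_qaly == pytest.approx(30.0)

    def test_discounted_cost_matches_geometric_series(self, config, params):
        params.state_cost_gbp["no_obstructive_cad"] = 100.0
        trace = run_cohort(_single_state_matrix(), [1.0], config, params, NO_TREAT)
        r = config.discount_rate_annual
        closed_form = 100.0 * sum((1 + r) ** (-t / 4) for t in range(config.n_cycles))
        assert trace.discounted_cost_gbp == pytest.approx(closed_form, abs=1e-9)

    def test_zero_discount_recovers_undiscounted_exactly(self, config, params):
        config.discount_rate_annual = 0.0
        matrix = _two_state_matrix(0.1)
        trace = run_cohort(matrix, [1.0, 0.0], config, params, NO_TREAT)
        assert trace.discounted_cost_gbp == trace.undiscounted_cost_gbp
        assert trace.discounted_qaly == trace.undiscounted_qaly

    def test_positive_discount_strictly_decreases_totals(self, config, params):
        matrix = _two_state_matrix(0.1)
        disc = run_cohort(matrix, [1.0, 0.0], config, params, NO_TREAT)
        config.discount_rate_annual = 0.0
        undisc = run_cohort(matrix, [1.0, 0.0], config, params, NO_TREAT)
        assert disc.discounted_cost_gbp < undisc.discounted_cost_gbp
        assert disc.discounted_qaly < undisc.discounted_qaly

    def test_mass_conservation_and_absorbing_monotonicity(self, config, params):
        effects = EffectInputs.from_parameters(params)
        for stratum in (S_NO, S_OB):
            matrix = build_transition_matrix(stratum, params, TreatmentState(0, 40), effects)
            initial = np.zeros(len(matrix.states))
            initial[0] = 1.0
            trace = run_cohort(matrix, initial, config, params, TreatmentState(0, 40))
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
            for dead in (HealthState.CARDIAC_DEATH, HealthState.OTHER_DEATH):
                occ = trace.occupancy[:, matrix.index(dead)]
                assert (np.diff(occ) >= -1e-15).all()

    def test_invalid_initial_distribution_rejected(self, config, params):
        with pytest.raises(NumericError):
            run_cohort(_two_state_matrix(0.1), [0.6, 0.6], config, params, NO_TREAT)

    def test_half_cycle_correction_uses_midpoint_occupancy(self, params):
        config = ModelConfig(horizon_years=1, discount_rate_annual=0.0)
        params.state_cost_gbp["no_obstructive_cad"] = 100.0
        params.utility["no_obstructive_cad"] = 1.0
        matrix = _two_state_matrix(0.5)
        plain = run_cohort(matrix, [1.0, 0.0], config, params, NO_TREAT)
        config.half_cycle_correction = True
        hcc = run_cohort(matrix, [1.0, 0.0], config, params, NO_TREAT)
        # alive occupancy 1, .5, .25, .125 -> midpoints .75, .375, .1875, .09375
        assert plain.discounted_cost_gbp == pytest.approx(187.5)
        assert hcc.discounted_cost_gbp == pytest.approx(140.625)
        assert hcc.discounted_qaly == pytest.approx(1.40625 * 0.25)


class TestExpectedEvents:
    def test_identity_matrix_has_no_events(self, config, params):
        trace = run_cohort(_single_state_matrix(), [1.0], config, params, NO_TREAT)
        assert all(v == 0.0 for v in expected_events(trace, 5000).values())

    def test_single_cycle_flow(self, params):
        config = ModelConfig(horizon_years=1, cycle_length_months=12)
        matrix = TransitionMatrix(
            (HealthState.OBSTRUCTIVE_CAD, HealthState.MI),
            np.array([[0.9, 0.1], [0.0, 1.0]]),
        )
        trace = run_cohort(matrix, [1.0, 0.0], config, params, NO_TREAT)
        assert expected_events(trace, 5000)["mi"] == pytest.approx(500.0)

    def test_totals_equal_cycle_wise_accumulation(self, config, params):
        effects = EffectInputs.from_parameters(params)
        matrix = build_transition_matrix(S_NO, params, NO_TREAT, effects)
        initial = np.zeros(len(matrix.states))
        initial[0] = 1.0
        trace = run_cohort(matrix, initial, config, params, NO_TREAT)
        events = expected_events(trace, 5000)
        for event in ("mi", "stroke", "heart_failure", "cardiac_death", "other_death"):
            j = matrix.index(HealthState(event))
            manual = sum(trace.event_flows[t, j] for t in range(config.n_cycles))
            assert events[event] == pytest.approx(5000 * manual)

    def test_nonpositive_population_rejected(self, config, params):
        trace = run_cohort(_single_state_matrix(), [1.0], config, params, NO_TREAT)
        with pytest.raises(NumericError):
            expected_events(trace, 0)


def test_trace_frame_layout(config, params):
    trace = run_cohort(_two_state_matrix(0.2), [1.0, 0.0], config, params, NO_TREAT)
    frame = trace_to_frame(trace)
    assert list(frame.columns) == ["cycle", "state", "occupancy"]
    assert len(frame) == (config.n_cycles + 1) * 2
    assert frame.groupby("cycle")["occupancy"].sum().round(12).eq(1.0).all()


def test_microsimulation_agrees_on_small_chain(config, params):
    matrix = TransitionMatrix(
        (HealthState.NO_OBSTRUCTIVE_CAD, HealthState.MI, HealthState.OTHER_DEATH),
        np.array([[0.96, 0.03, 0.01], [0.0, 0.97, 0.03], [0.0, 0.0, 1.0]]),
    )
    trace = run_cohort(matrix, [1.0, 0.0, 0.0], config, params, NO_TREAT)
    micro = microsimulate(matrix, [1.0, 0.0, 0.0], config, params, NO_TREAT,
                          n_agents=50_000, seed=99)
    assert abs(micro["cost_mean"] - trace.discounted_cost_gbp) < 3 * micro["cost_se"]
    assert abs(micro["qaly_mean"] - trace.discounted_qaly) < 3 * micro["qaly_se"]
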