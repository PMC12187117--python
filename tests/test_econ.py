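"""Incremental results, PSA/CEAC, tornado, and scenario analyses."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from ccta_cea import (
    Action,
    ArmResult,
    ConfigurationError,
    DistributionSpec,
    NumericError,
    ScenarioOptions,
    ceac,
    evaluate_strategies,
    icer,
    implied_delta_q,
    incremental_results,
    net_monetary_benefit,
    one_way_tornado,
    run_psa,
    run_scenarios,
)


def _null_change(params):
    params.ai_management_change = {
        s: {Action.INITIATE.value: 0.0, Action.INTENSIFY.value: 0.0,
            Action.NO_CHANGE.value: 1.0}
        for s in params.stratum_weights
    }
    return params


class TestIncrementalResults:
    def test_arm_cost_difference(self):
        ai = ArmResult(7563.0, 14.09, {})
        sc = ArmResult(7270.0, 13.88, {})
        ce = incremental_results(ai, sc)
        assert ce.delta_cost == pytest.approx(293.0)
        assert ce.delta_qaly == pytest.approx(0.21)
        assert ce.status == "icer"

    def test_identical_arms_flag_zero_delta_q(self):
        arm = ArmResult(1000.0, 10.0, {})
        ce = incremental_results(arm, arm)
        assert ce.delta_cost == 0.0 and ce.delta_qaly == 0.0
        assert ce.status == "zero_delta_q"
        assert ce.icer is None

    @given(st.floats(-1e4, 1e4), st.floats(-1e4, 1e4),
           st.floats(0.1, 20), st.floats(0.1, 20))
    def test_deltas_equal_subtraction(self, c_ai, c_sc, q_ai, q_sc):
        ce = incremental_results(ArmResult(c_ai, q_ai, {}), ArmResult(c_sc, q_sc, {}))
        assert ce.delta_cost == c_ai - c_sc
        assert ce.delta_qaly == q_ai - q_sc


class TestIcer:
    @pytest.mark.parametrize("dc,dq,value,status", [
        (200.0, 0.04, 5000.0, "icer"),
        (0.0, 0.1, 0.0, "icer"),
        (-50.0, 0.1, None, "dominant"),
        (50.0, -0.1, None, "dominated"),
        (100.0, 0.0, None, "zero_delta_q"),
    ])
    def test_cases(self, dc, dq, value, status):
        got_value, got_status = icer(dc, dq)
        assert got_status == status
        if value is None:
            assert got_value is None
        else:
            assert got_value == pytest.approx(value)


class TestImpliedDeltaQ:
    def test_published_table_row(self):
        assert implied_delta_q(293.0, 1371.0) == pytest.approx(0.2137, abs=1e-4)

    def test_nonpositive_icer_rejected(self):
        with pytest.raises(NumericError):
            implied_delta_q(100.0, 0.0)

    @given(st.floats(1.0, 1e4), st.floats(0.01, 10.0))
    def test_inverts_icer_exactly(self, dc, dq):
        value, status = icer(dc, dq)
        assert status == "icer"
        assert implied_delta_q(dc, value) == pytest.approx(dq, abs=1e-12)


class TestNetMonetaryBenefit:
    def test_zero_threshold(self):
        assert net_monetary_benefit(693.0, 0.21, 0.0) == -693.0

    def test_hand_arithmetic(self):
        assert net_monetary_benefit(693.0, 0.21, 20_000.0) == pytest.approx(3507.0)

    def test_zero_at_the_icer(self):
        assert net_monetary_benefit(500.0, 0.25, 500.0 / 0.25) == pytest.approx(0.0)


class TestNullEffectEquivalence:
    def test_identical_management_gives_price_only_difference(self, config, params):
        _null_change(params)
        _, _, ce = evaluate_strategies(config, params)
        assert ce.delta_qaly == 0.0
        assert ce.delta_cost == pytest.approx(config.ai_price_gbp, abs=1e-9)
        assert ce.status == "zero_delta_q"


class TestPsa:
    def test_point_mass_specs_reproduce_deterministic_result(self, config, params):
        config.n_psa_draws = 20
        _, _, det = evaluate_strategies(config, params)
        specs = [
            DistributionSpec("point_mass", "utility.mi", params.utility["mi"]),
            DistributionSpec("point_mass", "colchicine_rr", params.colchicine_rr),
        ]
        model = lambda p: evaluate_strategies(config, p)[2]
        psa = run_psa(model, params, specs, config, seed=5)
        assert np.all(psa.draws[:, 0] == det.delta_cost)
        assert np.all(psa.draws[:, 1] == det.delta_qaly)

    def test_fixed_seed_reproduces_draws(self, config, params, specs):
        config.n_psa_draws = 30
        model = lambda p: evaluate_strategies(config, p)[2]
        a = run_psa(model, params, specs, config, seed=7)
        b = run_psa(model, params, specs, config, seed=7)
        assert np.array_equal(a.draws, b.draws)
        c = run_psa(model, params, specs, config, seed=8)
        assert not np.array_equal(a.draws, c.draws)

    def test_unsatisfiable_spec_is_a_hard_error(self, config, params):
        config.n_psa_draws = 20
        bad = [DistributionSpec("point_mass", "utility.mi", 2.0)]
        model = lambda p: evaluate_strategies(config, p)[2]
        with pytest.raises(NumericError):
            run_psa(model, params, bad, config, seed=1)


@pytest.fixture(scope="module")
def psa_result():
    from ccta_cea import default_model_config, default_parameters, default_distribution_specs
    config = default_model_config()
    config.n_psa_draws = 200
    params = default_parameters()
    model = lambda p: evaluate_strategies(config, p)[2]
    return run_psa(model, params, default_distribution_specs(params), config, seed=11)


class TestCeac:
    def test_matches_brute_force_nmb_count(self, psa_result):
        for lam, prob in psa_result.ceac.items():
            manual = np.mean([
                net_monetary_benefit(dc, dq, lam) > 0 for dc, dq in psa_result.draws
            ])
            assert prob == manual

    def test_zero_threshold_counts_cost_saving_draws(self, psa_result):
        assert psa_result.ceac[0.0] == np.mean(psa_result.draws[:, 0] < 0)

    def test_monotone_when_all_draws_gain_qalys(self, psa_result):
        assert (psa_result.draws[:, 1] > 0).all()
        probs = [psa_result.ceac[lam] for lam in sorted(psa_result.ceac)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))


class TestTornado:
    def _model(self, config):
        return lambda p: evaluate_strategies(config, p)[2]

    def test_endpoints_equal_direct_reevaluation(self, config, params):
        from ccta_cea import set_param
        ranges = {"event_cost_gbp.mi": (4000.0, 6000.0)}
        bars = one_way_tornado(self._model(config), params, ranges)
        assert len(bars) == 1
        for tag, value in (("icer_low", 4000.0), ("icer_high", 6000.0)):
            p = params.copy()
            set_param(p, "event_cost_gbp.mi", value)
            _, _, ce = evaluate_strategies(config, p)
            assert bars[0][tag] == pytest.approx(ce.icer)

    def test_zero_width_range_gives_zero_width_bar(self, config, params):
        bars = one_way_tornado(self._model(config), params,
                               {"utility.mi": (0.72, 0.72)})
        assert bars[0]["spread"] == pytest.approx(0.0)

    def test_sorted_by_spread_descending(self, config, params):
        ranges = {
            "utility.mi": (0.72, 0.72),
            "event_cost_gbp.mi": (3000.0, 8000.0),
            "rr_per_mmol.mi:lt5": (0.70, 0.86),
        }
        bars = one_way_tornado(self._model(config), params, ranges)
        spreads = [b["spread"] for b in bars]
        assert spreads == sorted(spreads, reverse=True)

    def test_invalid_range_skipped_with_log(self, config, params, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="ccta_cea.econ"):
            bars = one_way_tornado(self._model(config), params,
                                   {"utility.mi": (1.2, 1.3)})
        assert bars == []
        assert any("skipping" in rec.message for rec in caplog.records)


class TestScenarios:
    def test_six_rows_in_reporting_order(self, config, params):
        table = run_scenarios(config, params)
        assert list(table["scenario"]) == [
            "base_case", "nice_compliance", "colchicine", "non_obstructive_only",
            "statin_effect_halved", "reclassification_halved",
        ]
        assert (table["status"] == "icer").all()

    def test_missing_nice_inputs_named(self, config, params):
        params.nice_baseline_management = None
        with pytest.raises(ConfigurationError, match="nice_baseline_management"):
            evaluate_strategies(config, params, ScenarioOptions(nice_comparator=True))

    def test_non_obstructive_scenario_renormalises_weights(self, config, params):
        ai, sc, ce = evaluate_strategies(
            config, params, ScenarioOptions(non_obstructive_only=True))
        # cheaper, healthier population than the full cohort
        _, sc_all, _ = evaluate_strategies(config, params)
        assert sc.qaly > sc_all.qaly
        assert ce.status == "icer"

    def test_null_effect_base_case_has_no_icer(self, config, params):
        _null_change(params)
        table = run_scenarios(config, params, scenarios=(ScenarioOptions(),))
        assert table.loc[0, "status"] == "zero_delta_q"
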