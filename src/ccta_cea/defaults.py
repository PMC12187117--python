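"""Illustrative default inputs for the cost-utility model.

The published analysis keeps its cost, utility, and transition values in
supplementary tables; the defaults here are an internally consistent,
clinically plausible stand-in with the documented headline structure:
about 20% of patients have obstructive CAD, overall MACE incidence near
0.007 per 3-month cycle, and AI-guided management change shares calibrated
exactly to 45% (real-world practice) and 39% (full guideline compliance).
All values are overridable through the configuration file.
"""
from __future__ import annotations

from .config import ModelConfig, ParameterSet, DistributionSpec
from .states import (
    ALL_STRATA,
    ABSORBING_STATES,
    Action,
    AiRisk,
    CadStatus,
    HealthState,
    MACE_STATES,
    RiskBand,
    Stratum,
    alive_states_for,
)
from .synth import GeneratorTruth

_S = {  # shorthand: (cad, risk) -> Stratum
    (c.value, r.value): Stratum(c, r) for c in CadStatus for r in AiRisk
}

#: Cohort composition: 20% obstructive CAD, risk mix richer among obstructive.
STRATUM_WEIGHTS = {
    _S[("non_obstructive", "low_medium")]: 0.48,
    _S[("non_obstructive", "high")]: 0.20,
    _S[("non_obstructive", "very_high")]: 0.12,
    _S[("obstructive", "low_medium")]: 0.08,
    _S[("obstructive", "high")]: 0.07,
    _S[("obstructive", "very_high")]: 0.05,
}

#: Total MACE probability per 3-month cycle, by stratum.
CYCLE_MACE_PROB = {
    _S[("non_obstructive", "low_medium")]: 0.003,
    _S[("non_obstructive", "high")]: 0.007,
    _S[("non_obstructive", "very_high")]: 0.014,
    _S[("obstructive", "low_medium")]: 0.006,
    _S[("obstructive", "high")]: 0.011,
    _S[("obstructive", "very_high")]: 0.020,
}

#: Share of MACE by type (MI / stroke / heart failure / cardiac death).
MACE_SPLIT = {
    HealthState.MI.value: 0.35,
    HealthState.STROKE.value: 0.15,
    HealthState.HEART_FAILURE.value: 0.30,
    HealthState.CARDIAC_DEATH.value: 0.20,
}

#: Non-cardiac death probability per cycle (constant; the model's closure).
OTHER_DEATH_CYCLE_PROB = 0.004
#: Progression no-obstructive -> obstructive CAD per cycle.
PROGRESSION_CYCLE_PROB = 0.004

#: Baseline statin dose mix under real-world practice, by stratum.
BASELINE_MANAGEMENT = {
    _S[("non_obstructive", "low_medium")]: {0: 0.80, 40: 0.15, 80: 0.05},
    _S[("non_obstructive", "high")]: {0: 0.65, 40: 0.25, 80: 0.10},
    _S[("non_obstructive", "very_high")]: {0: 0.50, 40: 0.30, 80: 0.20},
    _S[("obstructive", "low_medium")]: {0: 0.35, 40: 0.45, 80: 0.20},
    _S[("obstructive", "high")]: {0: 0.25, 40: 0.50, 80: 0.25},
    _S[("obstructive", "very_high")]: {0: 0.15, 40: 0.50, 80: 0.35},
}

#: Baseline dose mix under strict NICE-guideline management (less statin use
#: without obstructive CAD, near-universal consideration with it).
NICE_BASELINE_MANAGEMENT = {
    _S[("non_obstructive", "low_medium")]: {0: 0.90, 40: 0.08, 80: 0.02},
    _S[("non_obstructive", "high")]: {0: 0.80, 40: 0.15, 80: 0.05},
    _S[("non_obstructive", "very_high")]: {0: 0.70, 40: 0.20, 80: 0.10},
    _S[("obstructive", "low_medium")]: {0: 0.20, 40: 0.55, 80: 0.25},
    _S[("obstructive", "high")]: {0: 0.15, 40: 0.55, 80: 0.30},
    _S[("obstructive", "very_high")]: {0: 0.10, 40: 0.55, 80: 0.35},
}

# Raw clinician propensities to act on the AI report; calibrated at build
# time so the expected overall change share is exactly the survey headline.
_PROPENSITY_REAL = {
    _S[("non_obstructive", "low_medium")]: {"initiate": 0.47, "intensify": 0.26},
    _S[("non_obstructive", "high")]: {"initiate": 0.80, "intensify": 0.16},
    _S[("non_obstructive", "very_high")]: {"initiate": 0.85, "intensify": 0.15},
    _S[("obstructive", "low_medium")]: {"initiate": 0.45, "intensify": 0.54},
    _S[("obstructive", "high")]: {"initiate": 0.28, "intensify": 0.70},
    _S[("obstructive", "very_high")]: {"initiate": 0.15, "intensify": 0.85},
}
_PROPENSITY_NICE = {
    _S[("non_obstructive", "low_medium")]: {"initiate": 0.37, "intensify": 0.25},
    _S[("non_obstructive", "high")]: {"initiate": 0.55, "intensify": 0.30},
    _S[("non_obstructive", "very_high")]: {"initiate": 0.60, "intensify": 0.30},
    _S[("obstructive", "low_medium")]: {"initiate": 0.30, "intensify": 0.50},
    _S[("obstructive", "high")]: {"initiate": 0.30, "intensify": 0.55},
    _S[("obstructive", "very_high")]: {"initiate": 0.30, "intensify": 0.60},
}

REAL_WORLD_CHANGE_TARGET = 0.45
GUIDELINE_CHANGE_TARGET = 0.39


def default_hazards_per_month() -> dict:
    """Constant monthly hazards consistent with the per-cycle probabilities."""
    hazards = {}
    for stratum in ALL_STRATA:
        total = CYCLE_MACE_PROB[stratum]
        h = {event: total * share / 3.0 for event, share in MACE_SPLIT.items()}
        h[HealthState.OTHER_DEATH.value] = OTHER_DEATH_CYCLE_PROB / 3.0
        hazards[stratum] = h
    return hazards


def default_truth(kind: str = "real_world") -> GeneratorTruth:
    """Generating truth for the synthetic cohort and survey.

    ``kind`` selects the management context: ``"real_world"`` (calibrated to
    a 45% overall change share) or ``"guideline"`` (39%, NICE-compliant
    baseline management).
    """
    if kind == "real_world":
        baseline, propensity, target = (
            BASELINE_MANAGEMENT, _PROPENSITY_REAL, REAL_WORLD_CHANGE_TARGET)
    elif kind == "guideline":
        baseline, propensity, target = (
            NICE_BASELINE_MANAGEMENT, _PROPENSITY_NICE, GUIDELINE_CHANGE_TARGET)
    else:
        raise ValueError(f"unknown truth kind {kind!r}")
    truth = GeneratorTruth(
        stratum_weights=dict(STRATUM_WEIGHTS),
        hazard_per_month=default_hazards_per_month(),
        baseline_management={s: dict(d) for s, d in baseline.items()},
        management_propensity={s: dict(p) for s, p in propensity.items()},
    )
    return truth.calibrated(target)


def default_transition_probs() -> dict:
    """Per-cycle transition rows for every stratum.

    Event probabilities are identical from every alive state (equal first and
    subsequent event risk); the disease-free state additionally progresses to
    obstructive CAD; the stay probability is the row residual.
    """
    probs = {}
    for stratum in ALL_STRATA:
        events = {event.value: CYCLE_MACE_PROB[stratum] * MACE_SPLIT[event.value]
                  for event in MACE_STATES}
        events[HealthState.OTHER_DEATH.value] = OTHER_DEATH_CYCLE_PROB
        rows = {}
        for frm in alive_states_for(stratum):
            row = {to: p for to, p in events.items() if to != frm.value}
            if frm is HealthState.NO_OBSTRUCTIVE_CAD:
                row[HealthState.OBSTRUCTIVE_CAD.value] = PROGRESSION_CYCLE_PROB
            rows[frm.value] = row
        probs[stratum] = rows
    return probs


def default_parameters() -> ParameterSet:
    """The shipped illustrative parameter set (not the published one)."""
    real = default_truth("real_world")
    nice = default_truth("guideline")
    return ParameterSet(
        transition_probs=default_transition_probs(),
        state_cost_gbp={
            HealthState.NO_OBSTRUCTIVE_CAD.value: 30.0,
            HealthState.OBSTRUCTIVE_CAD.value: 80.0,
            HealthState.MI.value: 180.0,
            HealthState.STROKE.value: 350.0,
            HealthState.HEART_FAILURE.value: 420.0,
            HealthState.CARDIAC_DEATH.value: 0.0,
            HealthState.OTHER_DEATH.value: 0.0,
        },
        event_cost_gbp={
            HealthState.MI.value: 5000.0,
            HealthState.STROKE.value: 9500.0,
            HealthState.HEART_FAILURE.value: 4500.0,
            HealthState.CARDIAC_DEATH.value: 3500.0,
            HealthState.OTHER_DEATH.value: 0.0,
        },
        utility={
            HealthState.NO_OBSTRUCTIVE_CAD.value: 0.85,
            HealthState.OBSTRUCTIVE_CAD.value: 0.80,
            HealthState.MI.value: 0.72,
            HealthState.STROKE.value: 0.62,
            HealthState.HEART_FAILURE.value: 0.65,
            HealthState.CARDIAC_DEATH.value: 0.0,
            HealthState.OTHER_DEATH.value: 0.0,
        },
        # drug plus dispensing and lipid/liver monitoring, per 3-month cycle
        statin_cost_gbp_per_cycle={0: 0.0, 40: 16.0, 80: 24.0},
        colchicine_cost_gbp_per_cycle=12.0,
        stratum_weights=dict(STRATUM_WEIGHTS),
        baseline_management={s: dict(d) for s, d in BASELINE_MANAGEMENT.items()},
        ai_management_change={s: real.observed_action_probs(s) for s in ALL_STRATA},
        nice_baseline_management={s: dict(d) for s, d in NICE_BASELINE_MANAGEMENT.items()},
        ai_management_change_guideline={s: nice.observed_action_probs(s) for s in ALL_STRATA},
    )


def default_model_config() -> ModelConfig:
    return ModelConfig()


def parameters_from_estimates(transition_probs: dict | None = None,
                              ai_management_change: dict | None = None,
                              stratum_weights: dict | None = None,
                              base: ParameterSet | None = None) -> ParameterSet:
    """Assemble a ParameterSet from data-driven estimates.

    Estimated entries replace the corresponding fields of ``base`` (the
    default illustrative set if omitted); everything else — costs,
    utilities, treatment-effect inputs — is retained.
    """
    params = (base or default_parameters()).copy()
    if transition_probs is not None:
        params.transition_probs.update(transition_probs)
    if ai_management_change is not None:
        params.ai_management_change = {s: dict(a) for s, a in ai_management_change.items()}
    if stratum_weights is not None:
        params.stratum_weights = dict(stratum_weights)
    return params


def default_distribution_specs(params: ParameterSet | None = None) -> list[DistributionSpec]:
    """Conventional PSA specification over the default parameter set.

    Beta for utilities and per-cycle probabilities (SE 10% of the mean,
    3 percentage points for utilities), gamma for costs (SE 15%, 10% for
    drug costs), lognormal for relative risks (SE 3-4%). Management-change
    shares stay deterministic.
    """
    params = params or default_parameters()
    specs: list[DistributionSpec] = []
    for state, u in params.utility.items():
        if u > 0:
            specs.append(DistributionSpec("beta", f"utility.{state}", u, 0.03))
    for state, c in params.state_cost_gbp.items():
        if c > 0:
            specs.append(DistributionSpec("gamma", f"state_cost_gbp.{state}", c, 0.15 * c))
    for state, c in params.event_cost_gbp.items():
        if c > 0:
            specs.append(DistributionSpec("gamma", f"event_cost_gbp.{state}", c, 0.15 * c))
    for dose, c in params.statin_cost_gbp_per_cycle.items():
        if c > 0:
            specs.append(DistributionSpec(
                "gamma", f"statin_cost_gbp_per_cycle.{dose}", c, 0.10 * c))
    c = params.colchicine_cost_gbp_per_cycle
    specs.append(DistributionSpec("gamma", "colchicine_cost_gbp_per_cycle", c, 0.10 * c))

    for stratum, rows in params.transition_probs.items():
        events = sorted({to for row in rows.values() for to in row})
        for event in events:
            values = {row[event] for row in rows.values() if event in row}
            if len(values) == 1:  # shared per-stratum parameter
                m = values.pop()
                if m > 0:
                    specs.append(DistributionSpec(
                        "beta", f"stratum_event_prob.{stratum.key}.{event}", m, 0.10 * m))

    for (outcome, band), rr in params.rr_per_mmol.items():
        specs.append(DistributionSpec(
            "lognormal", f"rr_per_mmol.{outcome}:{band}", rr, 0.03 * rr))
    specs.append(DistributionSpec(
        "lognormal", "colchicine_rr", params.colchicine_rr, 0.04 * params.colchicine_rr))
    for spec in specs:
        spec.validate()
    return specs
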