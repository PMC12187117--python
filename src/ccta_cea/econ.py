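"""Incremental cost-effectiveness results, PSA, CEAC, tornado, scenarios.

The comparison is AI-risk-guided management (standard care plus the AI
analysis and the management changes it triggers) versus standard care
alone. Both arms share every parameter draw; the AI analysis price is
charged once at entry in the AI arm. The probabilistic sensitivity
analysis re-runs both arms per sampled parameter set; the CEAC reports,
for each willingness-to-pay threshold, the fraction of draws with positive
net monetary benefit (strict inequality; ties count as not cost-effective).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import ModelConfig, ParameterSet, DistributionSpec, set_param, validate_parameters
from .effects import EffectInputs, TreatmentState
from .errors import ConfigurationError, NumericError
from .markov import TransitionMatrix, build_transition_matrix, run_cohort, _per_cycle_vectors
from .states import (
    AiRisk,
    CadStatus,
    EVENT_STATES,
    Stratum,
    entry_state_for,
    states_for,
)
from .tree import Arm, enumerate_branches, scale_reclassification

log = logging.getLogger(__name__)

#: Canonical 7-state ordering used by the batched engine.
_CANONICAL = states_for(Stratum(CadStatus.NON_OBSTRUCTIVE, AiRisk.LOW_MEDIUM))


@dataclass
class ScenarioOptions:
    """Switches selecting the base case or one of the published scenarios."""

    name: str = "base_case"
    colchicine: bool = False
    statin_effect_multiplier: float = 1.0
    reclassification_factor: float = 1.0
    nice_comparator: bool = False
    non_obstructive_only: bool = False


#: Base case plus the five univariate scenarios, in reporting order.
SCENARIOS = (
    ScenarioOptions(name="base_case"),
    ScenarioOptions(name="nice_compliance", nice_comparator=True),
    ScenarioOptions(name="colchicine", colchicine=True),
    ScenarioOptions(name="non_obstructive_only", non_obstructive_only=True),
    ScenarioOptions(name="statin_effect_halved", statin_effect_multiplier=0.5),
    ScenarioOptions(name="reclassification_halved", reclassification_factor=0.5),
)


@dataclass
class ArmResult:
    """Discounted totals per patient entering one arm."""

    cost_gbp: float
    qaly: float
    events: dict  # event state -> expected events per patient (undiscounted)


@dataclass
class CEResult:
    cost_ai: float
    cost_sc: float
    qaly_ai: float
    qaly_sc: float
    delta_cost: float
    delta_qaly: float
    icer: float | None
    status: str  # icer | dominant | dominated | zero_delta_q


@dataclass
class PSAResult:
    draws: np.ndarray  # (n_draws, 2): delta cost, delta QALY
    ceac: dict         # threshold -> probability cost-effective
    seed: int
    n_resampled: int = 0


# ---------------------------------------------------------------------------
# incremental results

def icer(delta_cost: float, delta_qaly: float) -> tuple[float | None, str]:
    """ICER value and status flag; never silently divides by zero.

    Dominant: cheaper and more effective. Dominated: costlier and less
    effective. A zero QALY difference yields no numeric ICER.
    """
    if delta_qaly == 0.0:
        return None, "zero_delta_q"
    if delta_qaly > 0 and delta_cost < 0:
        return None, "dominant"
    if delta_qaly < 0 and delta_cost > 0:
        return None, "dominated"
    return delta_cost / delta_qaly, "icer"


def incremental_results(ai: ArmResult, sc: ArmResult) -> CEResult:
    dc = ai.cost_gbp - sc.cost_gbp
    dq = ai.qaly - sc.qaly
    value, status = icer(dc, dq)
    return CEResult(ai.cost_gbp, sc.cost_gbp, ai.qaly, sc.qaly, dc, dq, value, status)


def implied_delta_q(delta_cost: float, icer_value: float) -> float:
    """Invert the ICER definition: ΔQALY = ΔCost / ICER."""
    if icer_value <= 0:
        raise NumericError(f"ICER must be positive to invert, got {icer_value}")
    return delta_cost / icer_value


def net_monetary_benefit(delta_cost: float, delta_qaly: float, threshold: float) -> float:
    """NMB = threshold x ΔQALY - ΔCost."""
    if threshold < 0:
        raise NumericError(f"willingness-to-pay threshold must be >= 0, got {threshold}")
    return threshold * delta_qaly - delta_cost


# ---------------------------------------------------------------------------
# arm evaluation

def _arm_inputs(params: ParameterSet, options: ScenarioOptions):
    weights = dict(params.stratum_weights)
    if options.non_obstructive_only:
        weights = {s: w for s, w in weights.items()
                   if s.cad_status is CadStatus.NON_OBSTRUCTIVE}
        total = sum(weights.values())
        if total <= 0:
            raise ConfigurationError("no non-obstructive stratum weight to renormalise")
        weights = {s: w / total for s, w in weights.items()}
    if options.nice_comparator:
        if params.nice_baseline_management is None:
            raise ConfigurationError(
                "scenario nice_compliance requires parameters.nice_baseline_management")
        if params.ai_management_change_guideline is None:
            raise ConfigurationError(
                "scenario nice_compliance requires parameters.ai_management_change_guideline")
        baseline = params.nice_baseline_management
        change = params.ai_management_change_guideline
    else:
        baseline = params.baseline_management
        change = params.ai_management_change
    if options.reclassification_factor != 1.0:
        change = scale_reclassification(change, options.reclassification_factor)
    return weights, baseline, change


def _branches_for(arm: Arm, params: ParameterSet, options: ScenarioOptions):
    weights, baseline, change = _arm_inputs(params, options)
    return enumerate_branches(
        arm, weights, baseline,
        change if arm is Arm.AI_RISK else None,
        colchicine_scenario=options.colchicine and arm is Arm.AI_RISK,
    )


def _embed(vec: np.ndarray, idx: np.ndarray, size: int) -> np.ndarray:
    out = np.zeros(size)
    out[idx] = vec
    return out


def evaluate_arm(arm, config: ModelConfig, params: ParameterSet,
                 options: ScenarioOptions | None = None,
                 batched: bool = True) -> ArmResult:
    """Weighted discounted cost, QALYs, and expected events for one arm.

    ``batched=True`` runs all unique stratum x treatment chains in one
    vectorised pass; ``batched=False`` runs each branch through
    :func:`ccta_cea.markov.run_cohort` (reference path, used for validation).
    The AI analysis price is added once at entry in the AI arm.
    """
    arm = Arm(arm)
    options = options or ScenarioOptions()
    effects = EffectInputs.from_parameters(params, options.statin_effect_multiplier)
    branches = _branches_for(arm, params, options)

    merged: dict = {}
    for b in branches:
        key = (b.stratum, b.treatment)
        merged[key] = merged.get(key, 0.0) + b.weight

    if not batched:
        cost = qaly = 0.0
        events = {e.value: 0.0 for e in EVENT_STATES}
        for (stratum, treatment), w in merged.items():
            matrix = build_transition_matrix(stratum, params, treatment, effects)
            initial = np.zeros(len(matrix.states))
            initial[matrix.index(entry_state_for(stratum))] = 1.0
            trace = run_cohort(matrix, initial, config, params, treatment)
            cost += w * trace.discounted_cost_gbp
            qaly += w * trace.discounted_qaly
            totals = trace.event_flows.sum(axis=0)
            for e in EVENT_STATES:
                if e in matrix.states:
                    events[e.value] += w * totals[matrix.index(e)]
        if arm is Arm.AI_RISK:
            cost += config.ai_price_gbp
        return ArmResult(cost, qaly, events)

    # batched path: embed every chain into the canonical 7-state space
    S = len(_CANONICAL)
    keys = list(merged)
    B = len(keys)
    P = np.zeros((B, S, S))
    for i in range(S):
        P[:, i, i] = 1.0
    cost_vec = np.zeros((B, S))
    event_vec = np.zeros((B, S))
    util_vec = np.zeros((B, S))
    init = np.zeros((B, S))
    weights = np.array([merged[k] for k in keys])

    for b, (stratum, treatment) in enumerate(keys):
        matrix = build_transition_matrix(stratum, params, treatment, effects)
        idx = np.array([_CANONICAL.index(s) for s in matrix.states])
        P[b][np.ix_(idx, idx)] = matrix.probs
        c, e, u = _per_cycle_vectors(matrix, params, treatment, config.cycle_years)
        cost_vec[b] = _embed(c, idx, S)
        event_vec[b] = _embed(e, idx, S)
        util_vec[b] = _embed(u, idx, S)
        init[b, _CANONICAL.index(entry_state_for(stratum))] = 1.0

    offdiag = P.copy()
    di = np.arange(S)
    offdiag[:, di, di] = 0.0
    disc = config.discount_factors()
    hcc = config.half_cycle_correction

    occ = init
    dcost = np.zeros(B)
    dqaly = np.zeros(B)
    flows_total = np.zeros((B, S))
    for t in range(config.n_cycles):
        flows = np.einsum("bi,bij->bj", occ, offdiag)
        occ_next = np.einsum("bi,bij->bj", occ, P)
        occ_eff = 0.5 * (occ + occ_next) if hcc else occ
        dcost += disc[t] * ((occ_eff * cost_vec).sum(axis=1) + (flows * event_vec).sum(axis=1))
        dqaly += disc[t] * (occ_eff * util_vec).sum(axis=1)
        flows_total += flows
        occ = occ_next

    cost = float(weights @ dcost)
    qaly = float(weights @ dqaly)
    per_event = weights @ flows_total
    events = {e.value: float(per_event[_CANONICAL.index(e)]) for e in EVENT_STATES}
    if arm is Arm.AI_RISK:
        cost += config.ai_price_gbp
    return ArmResult(cost, qaly, events)


def evaluate_strategies(config: ModelConfig, params: ParameterSet,
                        options: ScenarioOptions | None = None,
                        batched: bool = True) -> tuple[ArmResult, ArmResult, CEResult]:
    """Run both arms on one parameter set and form incremental results."""
    options = options or ScenarioOptions()
    ai = evaluate_arm(Arm.AI_RISK, config, params, options, batched=batched)
    sc = evaluate_arm(Arm.STANDARD_CARE, config, params, options, batched=batched)
    return ai, sc, incremental_results(ai, sc)


def expected_event_table(ai: ArmResult, sc: ArmResult, n_patients: int) -> pd.DataFrame:
    """Fig-3-style table: events per ``n_patients`` by arm, with reductions."""
    rows = []
    for e in EVENT_STATES:
        e_ai = ai.events[e.value] * n_patients
        e_sc = sc.events[e.value] * n_patients
        rows.append({
            "event": e.value,
            "ai_risk": e_ai,
            "standard_care": e_sc,
            "events_averted": e_sc - e_ai,
            "pct_reduction": 100.0 * (e_sc - e_ai) / e_sc if e_sc else 0.0,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

_MAX_ATTEMPTS_PER_DRAW = 50


def run_psa(model, base_params: ParameterSet, specs: list[DistributionSpec],
            config: ModelConfig, seed: int | None = None) -> PSAResult:
    """Sample ``config.n_psa_draws`` parameter sets and re-run the model.

    ``model`` maps a :class:`ParameterSet` to a :class:`CEResult`; both arms
    must be evaluated inside it on the same draw. Draws violating parameter
    invariants are resampled (counted; a resample rate above 10% is a hard
    error). Fixed seed gives identical draws.
    """
    seed = config.seed if seed is None else seed
    for spec in specs:
        spec.validate()
    rng = np.random.default_rng(seed)
    n = config.n_psa_draws
    draws = np.empty((n, 2))
    n_resampled = 0
    for i in range(n):
        for _ in range(_MAX_ATTEMPTS_PER_DRAW):
            p = base_params.copy()
            for spec in specs:
                set_param(p, spec.target, spec.sample(rng))
            if not validate_parameters(p):
                break
            n_resampled += 1
            if n_resampled > 0.10 * n:
                raise NumericError(
                    f"PSA resample rate exceeded 10% after {i} draws; "
                    "check the distribution specification"
                )
        else:
            raise NumericError(f"PSA draw {i}: no valid sample in {_MAX_ATTEMPTS_PER_DRAW} attempts")
        res = model(p)
        draws[i] = (res.delta_cost, res.delta_qaly)
    if n_resampled:
        log.info("PSA: %d invalid draws resampled", n_resampled)
    result = PSAResult(draws=draws, ceac={}, seed=seed, n_resampled=n_resampled)
    result.ceac = ceac(result, config.wtp_thresholds_gbp)
    return result


def ceac(psa: PSAResult, thresholds) -> dict:
    """Probability cost-effective: fraction of draws with NMB > 0 per threshold."""
    if len(psa.draws) == 0:
        raise NumericError("CEAC requires at least one PSA draw")
    dc, dq = psa.draws[:, 0], psa.draws[:, 1]
    return {
        float(lam): float(np.mean(lam * dq - dc > 0.0))
        for lam in thresholds
    }


# ---------------------------------------------------------------------------
# one-way (tornado) sensitivity analysis

def one_way_tornado(model, base_params: ParameterSet, param_ranges: dict) -> list[dict]:
    """Vary each parameter alone to its bounds; sort by ICER spread.

    ``param_ranges`` maps a dotted parameter path to (low, high). Ranges that
    violate parameter invariants are skipped with a log entry. Returns bars
    sorted by \\|icer_high - icer_low\\| descending.
    """
    bars = []
    for path, (low, high) in param_ranges.items():
        icers = {}
        skip = False
        for tag, value in (("low", low), ("high", high)):
            p = base_params.copy()
            set_param(p, path, value)
            violations = validate_parameters(p)
            if violations:
                log.warning("tornado: skipping %s=%s (%s)", path, value, violations[0])
                skip = True
                break
            res = model(p)
            icers[tag] = res.icer if res.status == "icer" else np.nan
        if skip:
            continue
        spread = abs(icers["high"] - icers["low"])
        bars.append({
            "parameter": path,
            "low": low,
            "high": high,
            "icer_low": icers["low"],
            "icer_high": icers["high"],
            "spread": 0.0 if np.isnan(spread) else float(spread),
        })
    return sorted(bars, key=lambda b: b["spread"], reverse=True)


# ---------------------------------------------------------------------------
# scenario analyses

def run_scenarios(config: ModelConfig, params: ParameterSet,
                  scenarios=SCENARIOS) -> pd.DataFrame:
    """Base case plus the five univariate scenarios, one CEResult per row."""
    rows = []
    for options in scenarios:
        ai, sc, ce = evaluate_strategies(config, params, options)
        rows.append({
            "scenario": options.name,
            "cost_ai": ce.cost_ai,
            "cost_sc": ce.cost_sc,
            "qaly_ai": ce.qaly_ai,
            "qaly_sc": ce.qaly_sc,
            "delta_cost": ce.delta_cost,
            "delta_qaly": ce.delta_qaly,
            "icer": ce.icer,
            "status": ce.status,
        })
    return pd.DataFrame(rows)
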