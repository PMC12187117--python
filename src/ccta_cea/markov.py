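"""Population-cohort Markov engine.

Builds treatment-adjusted per-cycle transition matrices, iterates the
cohort over the model horizon, and accumulates discounted costs and QALYs
plus undiscounted incident event flows. Event costs are charged on the
incident flow in the cycle of transition; chronic state costs, drug costs,
and utilities accrue per cycle of occupancy; cycle-0 accruals are
undiscounted. An individual-level microsimulation of the same chain is
provided as an independent cross-check.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig, ParameterSet
from .effects import EffectInputs, TreatmentState, mace_relative_risks
from .errors import InvalidRateError, NumericError
from .states import (
    ABSORBING_STATES,
    EVENT_STATES,
    HealthState,
    MACE_STATES,
    Stratum,
    states_for,
)

_ROW_TOL = 1e-12


@dataclass
class TransitionMatrix:
    """Square per-cycle transition matrix over an ordered state list."""

    states: tuple
    probs: np.ndarray

    def validate(self) -> None:
        n = len(self.states)
        if self.probs.shape != (n, n):
            raise NumericError(f"matrix shape {self.probs.shape} does not match {n} states")
        if (self.probs < -_ROW_TOL).any() or (self.probs > 1 + _ROW_TOL).any():
            raise NumericError("transition probabilities outside [0, 1]")
        sums = self.probs.sum(axis=1)
        bad = np.abs(sums - 1.0) > 1e-9
        if bad.any():
            state = self.states[int(np.argmax(bad))]
            raise NumericError(f"row {state} sums to {sums[bad][0]!r}, expected 1")
        for i, s in enumerate(self.states):
            if s in ABSORBING_STATES:
                unit = np.zeros(n)
                unit[i] = 1.0
                if not np.array_equal(self.probs[i], unit):
                    raise NumericError(f"death row {s} is not absorbing")

    def index(self, state) -> int:
        return self.states.index(state)


@dataclass
class CohortTrace:
    """Cycle-by-cycle occupancy and accumulated outcomes for one branch."""

    states: tuple
    occupancy: np.ndarray       # (n_cycles + 1, n_states), each row sums to 1
    event_flows: np.ndarray     # (n_cycles, n_states), incident fractions
    discounted_cost_gbp: float
    discounted_qaly: float
    undiscounted_cost_gbp: float
    undiscounted_qaly: float


def build_transition_matrix(stratum: Stratum, params: ParameterSet,
                            treatment: TreatmentState,
                            effects: EffectInputs) -> TransitionMatrix:
    """Treatment-adjusted transition matrix for one stratum.

    MACE transition probabilities are baseline x RR(treatment); the stay
    probability absorbs the difference so every row sums to one. Death rows
    are absorbing. Raises :class:`InvalidRateError` if an adjusted row
    exceeds probability one.
    """
    states = states_for(stratum)
    n = len(states)
    rr = mace_relative_risks(treatment, stratum, effects)
    rows = params.transition_probs[stratum]
    P = np.zeros((n, n))
    pos = {s.value: i for i, s in enumerate(states)}
    mace = {s.value for s in MACE_STATES}
    for i, s in enumerate(states):
        if s in ABSORBING_STATES:
            P[i, i] = 1.0
            continue
        row = rows.get(s.value, {})
        total = 0.0
        for to, p in row.items():
            p_adj = p * rr[to] if to in mace else p
            P[i, pos[to]] = p_adj
            total += p_adj
        if total > 1.0 + _ROW_TOL:
            raise InvalidRateError(
                f"{stratum} row {s.value}: adjusted transition mass {total:.6f} > 1"
            )
        P[i, i] = 1.0 - total
    matrix = TransitionMatrix(states, P)
    matrix.validate()
    return matrix


def _per_cycle_vectors(matrix: TransitionMatrix, params: ParameterSet,
                       treatment: TreatmentState, cycle_years: float):
    """State-indexed cost/utility/drug vectors for one branch."""
    states = matrix.states
    state_cost = np.array([params.state_cost_gbp.get(s.value, 0.0) for s in states])
    event_cost = np.array([params.event_cost_gbp.get(s.value, 0.0) for s in states])
    utility = np.array([params.utility.get(s.value, 0.0) for s in states]) * cycle_years
    alive = np.array([s not in ABSORBING_STATES for s in states], dtype=float)
    drug = params.statin_cost_gbp_per_cycle.get(treatment.dose_to_mg, 0.0)
    if treatment.colchicine:
        drug += params.colchicine_cost_gbp_per_cycle
    cycle_cost = state_cost + drug * alive
    return cycle_cost, event_cost, utility


def run_cohort(matrix: TransitionMatrix, initial, config: ModelConfig,
               params: ParameterSet, treatment: TreatmentState) -> CohortTrace:
    """Iterate one branch of the cohort over the model horizon.

    ``initial`` is a distribution over ``matrix.states``. Per cycle, costs =
    occupancy x (state + drug costs) + incident flows x event costs; QALYs =
    occupancy x utility x cycle length in years; both discounted at the
    annual rate compounded per cycle. With half-cycle correction on,
    occupancy-based accruals use the midpoint of adjacent cycles.
    """
    initial = np.asarray(initial, dtype=float)
    n = len(matrix.states)
    if initial.shape != (n,) or abs(initial.sum() - 1.0) > 1e-9 or (initial < 0).any():
        raise NumericError("initial state vector is not a distribution over the states")
    matrix.validate()

    T = config.n_cycles
    P = matrix.probs
    offdiag = P - np.diag(np.diag(P))
    cycle_cost, event_cost, utility = _per_cycle_vectors(
        matrix, params, treatment, config.cycle_years)
    disc = config.discount_factors()

    occupancy = np.empty((T + 1, n))
    occupancy[0] = initial
    flows = np.empty((T, n))
    for t in range(T):
        flows[t] = occupancy[t] @ offdiag
        occupancy[t + 1] = occupancy[t] @ P

    occ_eff = occupancy[:-1]
    if config.half_cycle_correction:
        occ_eff = 0.5 * (occupancy[:-1] + occupancy[1:])

    cost_per_cycle = occ_eff @ cycle_cost + flows @ event_cost
    qaly_per_cycle = occ_eff @ utility
    ones = np.ones_like(disc)  # same summation path, so r=0 is exact
    return CohortTrace(
        states=matrix.states,
        occupancy=occupancy,
        event_flows=flows,
        discounted_cost_gbp=float(disc @ cost_per_cycle),
        discounted_qaly=float(disc @ qaly_per_cycle),
        undiscounted_cost_gbp=float(ones @ cost_per_cycle),
        undiscounted_qaly=float(ones @ qaly_per_cycle),
    )


def expected_events(trace: CohortTrace, n_patients: int) -> dict:
    """Expected event counts per ``n_patients``: undiscounted cumulative
    incident flows into each event state."""
    if n_patients <= 0:
        raise NumericError(f"n_patients must be positive, got {n_patients}")
    totals = trace.event_flows.sum(axis=0)
    return {
        e.value: float(totals[trace.states.index(e)]) * n_patients
        for e in EVENT_STATES
        if e in trace.states
    }


def trace_to_frame(trace: CohortTrace) -> pd.DataFrame:
    """Delimited-text export: (cycle, state, occupancy)."""
    cycles, states = trace.occupancy.shape
    return pd.DataFrame({
        "cycle": np.repeat(np.arange(cycles), states),
        "state": [s.value for s in trace.states] * cycles,
        "occupancy": trace.occupancy.ravel(),
    })


def microsimulate(matrix: TransitionMatrix, initial, config: ModelConfig,
                  params: ParameterSet, treatment: TreatmentState,
                  n_agents: int, seed: int) -> dict:
    """Individual-level Monte-Carlo simulation of the same chain.

    Returns means and Monte-Carlo standard errors of per-agent discounted
    cost and QALYs, plus final-cycle state occupancy fractions. Used as an
    independent oracle for :func:`run_cohort` (same costing conventions,
    half-cycle correction unsupported).
    """
    if config.half_cycle_correction:
        raise NumericError("microsimulation does not implement half-cycle correction")
    rng = np.random.default_rng(seed)
    matrix.validate()
    n_states = len(matrix.states)
    cum = matrix.probs.cumsum(axis=1)
    cycle_cost, event_cost, utility = _per_cycle_vectors(
        matrix, params, treatment, config.cycle_years)
    disc = config.discount_factors()

    state = rng.choice(n_states, size=n_agents, p=np.asarray(initial, dtype=float))
    cost = np.zeros(n_agents)
    qaly = np.zeros(n_agents)
    for t in range(config.n_cycles):
        cost += disc[t] * cycle_cost[state]
        qaly += disc[t] * utility[state]
        u = rng.random(n_agents)
        nxt = np.empty(n_agents, dtype=int)
        for s in np.unique(state):
            mask = state == s
            nxt[mask] = np.searchsorted(cum[s], u[mask], side="right")
        moved = nxt != state
        cost[moved] += disc[t] * event_cost[nxt[moved]]
        state = nxt

    occupancy = np.bincount(state, minlength=n_states) / n_agents
    occ_se = np.sqrt(occupancy * (1 - occupancy) / n_agents)
    return {
        "cost_mean": float(cost.mean()),
        "cost_se": float(cost.std(ddof=1) / np.sqrt(n_agents)),
        "qaly_mean": float(qaly.mean()),
        "qaly_se": float(qaly.std(ddof=1) / np.sqrt(n_agents)),
        "final_occupancy": occupancy,
        "final_occupancy_se": occ_se,
    }
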