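"""Transition and management-change probabilities from patient-level data.

Implements the crude events-per-life-months rule: per-cycle probability =
cycle length x total events / total months alive, applied per stratum and
event type, with the same probability for first and subsequent events.
"""
from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .config import ModelConfig
from .errors import DataError, InvalidRateError
from .states import Action, HealthState, Stratum, alive_states_for
from .synth import EVENT_TYPES, FATAL_EVENTS

_COUNT_COLUMNS = {
    HealthState.MI.value: "n_mi",
    HealthState.STROKE.value: "n_stroke",
    HealthState.HEART_FAILURE.value: "n_heart_failure",
    HealthState.CARDIAC_DEATH.value: "n_cardiac_death",
    HealthState.OTHER_DEATH.value: "n_other_death",
}


def total_life_months(cohort: pd.DataFrame) -> float:
    """Accumulated months alive across the cohort.

    Death truncates life months at the event month; non-fatal events do not —
    patients keep accruing alive time until censoring.
    """
    if len(cohort) == 0:
        warnings.warn("empty cohort: total life months is 0", stacklevel=2)
        return 0.0
    fatal = cohort["event_type"].isin(FATAL_EVENTS)
    months = np.where(fatal, cohort["event_month"], cohort["followup_months"])
    return float(months.sum())


def per_cycle_event_probability(events: int, life_months: float,
                                cycle_length_months: int) -> float:
    """Linear rule: cycle length x events / life months."""
    if life_months <= 0:
        raise DataError(f"life months must be positive, got {life_months}")
    if events < 0:
        raise DataError(f"event count must be >= 0, got {events}")
    p = cycle_length_months * events / life_months
    if p > 1.0:
        raise InvalidRateError(
            f"{events} events over {life_months} life months gives per-cycle "
            f"probability {p:.4f} > 1; use a shorter cycle or the exponential conversion"
        )
    return p


def rate_to_probability(rate_per_month: float, cycle_length_months: int,
                        method: str = "linear") -> float:
    """Convert a monthly rate to a per-cycle probability."""
    if method == "linear":
        p = rate_per_month * cycle_length_months
        if p > 1.0:
            raise InvalidRateError(f"linear conversion gives {p:.4f} > 1")
        return p
    if method == "exponential":
        return 1.0 - math.exp(-rate_per_month * cycle_length_months)
    raise DataError(f"unknown conversion method {method!r}")


def _event_counts(group: pd.DataFrame) -> dict:
    """Per-type event totals for one stratum.

    Prefers the per-type count columns (all events over the observed alive
    time); falls back to first-event tallies if the counts are absent.
    """
    if set(_COUNT_COLUMNS.values()) <= set(group.columns):
        return {e: int(group[col].sum()) for e, col in _COUNT_COLUMNS.items()}
    tally = group["event_type"].value_counts()
    return {e: int(tally.get(e, 0)) for e in EVENT_TYPES}


def estimate_transition_probabilities(cohort: pd.DataFrame, config: ModelConfig,
                                      progression_prob: float = 0.0) -> dict:
    """Per-stratum transition rows estimated from a cohort table.

    Returns stratum -> from-state -> to-state -> per-cycle probability, with
    the same event probabilities from every alive state. Strata absent from
    the cohort are omitted (missing, not zero) with a warning.
    ``progression_prob`` supplies the disease-progression entry the cohort
    cannot identify (no-obstructive -> obstructive CAD).
    """
    if len(cohort) == 0:
        raise DataError("cannot estimate transition probabilities from an empty cohort")
    method = config.rate_conversion
    cl = config.cycle_length_months
    out: dict = {}
    grouped = dict(tuple(cohort.groupby(["cad_status", "ai_risk"], sort=True)))
    for stratum_key, group in grouped.items():
        stratum = Stratum.parse(":".join(stratum_key))
        life = total_life_months(group)
        counts = _event_counts(group)
        events = {}
        for e, n in counts.items():
            if method == "linear":
                events[e] = per_cycle_event_probability(n, life, cl)
            else:
                events[e] = rate_to_probability(n / life, cl, "exponential")
        rows = {}
        for frm in alive_states_for(stratum):
            row = {to: p for to, p in events.items() if to != frm.value}
            if frm is HealthState.NO_OBSTRUCTIVE_CAD and progression_prob > 0:
                row[HealthState.OBSTRUCTIVE_CAD.value] = progression_prob
            rows[frm.value] = row
        out[stratum] = rows
    from .states import ALL_STRATA
    missing = [s for s in ALL_STRATA if s not in out]
    if missing:
        warnings.warn(
            "no cohort rows for strata: " + ", ".join(s.key for s in missing)
            + "; their probabilities are missing, not zero",
            stacklevel=2,
        )
    return out


def estimate_management_probabilities(survey: pd.DataFrame) -> tuple[dict, float]:
    """Observed per-stratum action shares and the overall changed fraction.

    Returns ``(stratum -> {initiate, intensify, no_change}, overall_changed)``
    where shares are multinomial proportions of survey records. Strata with
    no records are omitted (missing, not zero).
    """
    if len(survey) == 0:
        raise DataError("cannot estimate management probabilities from an empty survey")
    out: dict = {}
    for stratum_key, group in survey.groupby(["cad_status", "ai_risk"], sort=True):
        stratum = Stratum.parse(":".join(stratum_key))
        n = len(group)
        tally = group["ai_action"].value_counts()
        out[stratum] = {a.value: float(tally.get(a.value, 0)) / n for a in Action}
    changed = (survey["ai_action"] != Action.NO_CHANGE.value).mean()
    return out, float(changed)


# ---------------------------------------------------------------------------
# delimited-text export

def transition_probs_to_frame(transition_probs: dict) -> pd.DataFrame:
    rows = [
        {"stratum": stratum.key, "from_state": frm, "to_state": to, "probability": p}
        for stratum, by_from in sorted(transition_probs.items(), key=lambda kv: kv[0].key)
        for frm, row in by_from.items()
        for to, p in row.items()
    ]
    return pd.DataFrame(rows, columns=["stratum", "from_state", "to_state", "probability"])


def transition_probs_from_frame(df: pd.DataFrame) -> dict:
    out: dict = {}
    for _, row in df.iterrows():
        stratum = Stratum.parse(row["stratum"])
        out.setdefault(stratum, {}).setdefault(row["from_state"], {})[row["to_state"]] = float(
            row["probability"]
        )
    return out
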