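"""Core vocabulary: CAD status, AI risk categories, health states, strata.

Patients entering the model are cross-classified by the presence of
obstructive coronary artery disease on CCTA and by a three-level AI risk
category (low/medium, high, very high), giving six strata. Within each
stratum the cohort moves through a fixed set of health states once per
model cycle; for patients with obstructive CAD at baseline the
disease-free state does not exist and is dropped.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass


class CadStatus(str, enum.Enum):
    OBSTRUCTIVE = "obstructive"
    NON_OBSTRUCTIVE = "non_obstructive"


class AiRisk(str, enum.Enum):
    LOW_MEDIUM = "low_medium"
    HIGH = "high"
    VERY_HIGH = "very_high"


class RiskBand(str, enum.Enum):
    """Baseline absolute-risk band used to key per-mmol treatment effects."""

    LT5 = "lt5"          # predicted baseline risk < 5%
    FROM5TO10 = "5to10"  # 5% to < 10%
    GE10 = "ge10"        # >= 10%


#: AI risk category -> baseline absolute-risk band for treatment effects.
RISK_BAND_FOR = {
    AiRisk.LOW_MEDIUM: RiskBand.LT5,
    AiRisk.HIGH: RiskBand.FROM5TO10,
    AiRisk.VERY_HIGH: RiskBand.GE10,
}


class HealthState(str, enum.Enum):
    NO_OBSTRUCTIVE_CAD = "no_obstructive_cad"
    OBSTRUCTIVE_CAD = "obstructive_cad"
    MI = "mi"
    STROKE = "stroke"
    HEART_FAILURE = "heart_failure"
    CARDIAC_DEATH = "cardiac_death"
    OTHER_DEATH = "other_death"


#: Major adverse cardiac event states, in canonical order.
MACE_STATES = (
    HealthState.MI,
    HealthState.STROKE,
    HealthState.HEART_FAILURE,
    HealthState.CARDIAC_DEATH,
)

#: Event states (MACE plus non-cardiac death).
EVENT_STATES = MACE_STATES + (HealthState.OTHER_DEATH,)

ABSORBING_STATES = (HealthState.CARDIAC_DEATH, HealthState.OTHER_DEATH)


class Action(str, enum.Enum):
    """Management change triggered by the AI risk report."""

    INITIATE = "initiate"      # statin 0 -> 40 mg
    INTENSIFY = "intensify"    # statin 40 -> 80 mg
    NO_CHANGE = "no_change"


STATIN_DOSES = (0, 40, 80)


@dataclass(frozen=True, order=True)
class Stratum:
    """One of the six CAD status x AI risk cells."""

    cad_status: CadStatus
    ai_risk: AiRisk

    @property
    def key(self) -> str:
        return f"{self.cad_status.value}:{self.ai_risk.value}"

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.key

    @property
    def risk_band(self) -> RiskBand:
        return RISK_BAND_FOR[self.ai_risk]

    @classmethod
    def parse(cls, key: str) -> "Stratum":
        try:
            cad, risk = key.split(":")
            return cls(CadStatus(cad), AiRisk(risk))
        except ValueError as exc:
            raise ValueError(f"not a stratum key: {key!r}") from exc


ALL_STRATA = tuple(
    Stratum(cad, risk)
    for cad in (CadStatus.NON_OBSTRUCTIVE, CadStatus.OBSTRUCTIVE)
    for risk in AiRisk
)


def states_for(stratum: Stratum) -> tuple[HealthState, ...]:
    """Ordered health states of the Markov model for one stratum.

    For obstructive-CAD strata the disease-free state is dropped and the
    cohort enters in the obstructive-CAD state.
    """
    if stratum.cad_status is CadStatus.OBSTRUCTIVE:
        return (HealthState.OBSTRUCTIVE_CAD,) + EVENT_STATES
    return (HealthState.NO_OBSTRUCTIVE_CAD, HealthState.OBSTRUCTIVE_CAD) + EVENT_STATES


def alive_states_for(stratum: Stratum) -> tuple[HealthState, ...]:
    return tuple(s for s in states_for(stratum) if s not in ABSORBING_STATES)


def entry_state_for(stratum: Stratum) -> HealthState:
    return states_for(stratum)[0]
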