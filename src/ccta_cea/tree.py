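"""Decision tree: expand each comparator arm into weighted Markov entries.

Each arm (AI-risk-guided vs standard care) becomes a set of leaves
(stratum, treatment state, weight) that seed the Markov model. Under
standard care patients keep their baseline statin dose; under AI guidance
the per-stratum observed change shares move mass from dose 0 to 40 mg
(initiate) and 40 to 80 mg (intensify). Patients already on 80 mg cannot
escalate. In the colchicine scenario, very-high-risk patients whose statin
management changed also receive colchicine.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import pandas as pd

from .effects import TreatmentState
from .errors import ConfigurationError
from .states import Action, AiRisk, Stratum

log = logging.getLogger(__name__)

_SUM_TOL = 1e-9


class Arm(str, enum.Enum):
    AI_RISK = "ai_risk"
    STANDARD_CARE = "standard_care"


@dataclass(frozen=True)
class Branch:
    arm: Arm
    stratum: Stratum
    treatment: TreatmentState
    weight: float


def enumerate_branches(arm: Arm, stratum_weights: dict, baseline_management: dict,
                       ai_management_change: dict | None = None,
                       colchicine_scenario: bool = False) -> list[Branch]:
    """Weighted decision-tree leaves for one arm.

    ``ai_management_change`` holds observed per-stratum shares of patients
    initiating (taken out of the dose-0 mass) and intensifying (out of the
    dose-40 mass); it is required only for the AI arm. A change share with no
    eligible baseline-dose mass to draw from is a configuration error.
    """
    arm = Arm(arm)
    if arm is Arm.AI_RISK and ai_management_change is None:
        raise ConfigurationError("ai_management_change is required for the ai_risk arm")

    total_w = sum(stratum_weights.values())
    if abs(total_w - 1.0) > _SUM_TOL:
        raise ConfigurationError(f"stratum weights sum to {total_w}, expected 1")

    leaves: dict[tuple, float] = {}

    def add(stratum, treatment, weight):
        if weight <= 0:
            return
        key = (stratum, treatment)
        leaves[key] = leaves.get(key, 0.0) + weight

    for stratum, w in stratum_weights.items():
        if w == 0:
            continue
        doses = baseline_management[stratum]
        if arm is Arm.STANDARD_CARE:
            for dose, p in doses.items():
                add(stratum, TreatmentState(dose, dose), w * p)
            continue

        acts = ai_management_change[stratum]
        init = acts.get(Action.INITIATE.value, 0.0)
        intens = acts.get(Action.INTENSIFY.value, 0.0)
        if init > doses.get(0, 0.0) + _SUM_TOL:
            raise ConfigurationError(
                f"{stratum}: initiate share {init} exceeds baseline dose-0 mass {doses.get(0, 0.0)}"
            )
        if intens > doses.get(40, 0.0) + _SUM_TOL:
            raise ConfigurationError(
                f"{stratum}: intensify share {intens} exceeds baseline dose-40 mass "
                f"{doses.get(40, 0.0)}"
            )
        if doses.get(80, 0.0) > 0:
            log.debug("%s: dose-80 mass %.3f cannot escalate; stays no_change",
                      stratum, doses[80])
        colch = colchicine_scenario and stratum.ai_risk is AiRisk.VERY_HIGH
        add(stratum, TreatmentState(0, 40, colch), w * init)
        add(stratum, TreatmentState(40, 80, colch), w * intens)
        add(stratum, TreatmentState(0, 0), w * (doses.get(0, 0.0) - init))
        add(stratum, TreatmentState(40, 40), w * (doses.get(40, 0.0) - intens))
        add(stratum, TreatmentState(80, 80), w * doses.get(80, 0.0))

    branches = [Branch(arm, s, t, wt) for (s, t), wt in leaves.items()]
    total = sum(b.weight for b in branches)
    if abs(total - 1.0) > _SUM_TOL:
        raise ConfigurationError(f"{arm.value} branch weights sum to {total}, expected 1")
    return branches


def scale_reclassification(ai_management_change: dict, factor: float) -> dict:
    """Multiply initiate/intensify shares by ``factor``; no_change absorbs
    the remainder so each distribution still sums to 1."""
    if not 0.0 <= factor <= 1.0:
        raise ConfigurationError(f"reclassification factor must be in [0, 1], got {factor}")
    out = {}
    for stratum, acts in ai_management_change.items():
        init = acts.get(Action.INITIATE.value, 0.0) * factor
        intens = acts.get(Action.INTENSIFY.value, 0.0) * factor
        out[stratum] = {
            Action.INITIATE.value: init,
            Action.INTENSIFY.value: intens,
            Action.NO_CHANGE.value: 1.0 - init - intens,
        }
    return out


def halve_reclassification(ai_management_change: dict) -> dict:
    """The halved-reclassification scenario: change shares x 0.5."""
    return scale_reclassification(ai_management_change, 0.5)


def branches_to_frame(branches: list[Branch]) -> pd.DataFrame:
    """Audit export: one row per leaf."""
    rows = [
        {
            "arm": b.arm.value,
            "stratum": b.stratum.key,
            "dose_from_mg": b.treatment.dose_from_mg,
            "dose_to_mg": b.treatment.dose_to_mg,
            "colchicine": b.treatment.colchicine,
            "weight": b.weight,
        }
        for b in sorted(branches, key=lambda b: (b.stratum.key, b.treatment.dose_from_mg,
                                                 b.treatment.dose_to_mg, b.treatment.colchicine))
    ]
    return pd.DataFrame(rows)
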