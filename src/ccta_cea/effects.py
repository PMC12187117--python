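"""Relative risks for statin and colchicine management changes.

Statin effects follow LDL-reduction arithmetic: atorvastatin lowers LDL by
48% (40 mg) or 53% (80 mg) from a 3.7 mmol/L baseline, and each mmol/L of
LDL lowering multiplies MACE risk by a per-mmol relative risk (log-linear,
default 0.78/mmol), keyed by outcome and baseline absolute-risk band. The
relative risk attaches to the *change* in dose: patients whose management
does not change keep RR = 1, because their existing treatment is already
reflected in the baseline transition probabilities.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError
from .states import MACE_STATES, STATIN_DOSES, Stratum


@dataclass(frozen=True)
class TreatmentState:
    """Statin management change (from/to dose) plus optional colchicine."""

    dose_from_mg: int
    dose_to_mg: int
    colchicine: bool = False

    def __post_init__(self):
        if self.dose_from_mg not in STATIN_DOSES or self.dose_to_mg not in STATIN_DOSES:
            raise ConfigurationError(
                f"statin doses must be in {STATIN_DOSES}: {self.dose_from_mg}->{self.dose_to_mg}"
            )
        if self.dose_to_mg < self.dose_from_mg:
            raise ConfigurationError(
                f"statin de-escalation is not modelled: {self.dose_from_mg}->{self.dose_to_mg}"
            )

    @property
    def changed(self) -> bool:
        return self.dose_to_mg != self.dose_from_mg


@dataclass
class EffectInputs:
    """Inputs to the LDL-based relative-risk derivation."""

    baseline_ldl_mmol: float = 3.7
    pct_reduction: dict = field(default_factory=lambda: {40: 0.48, 80: 0.53})
    rr_per_mmol: dict = field(default_factory=dict)
    statin_effect_multiplier: float = 1.0  # 0.5 models a halved statin effect
    colchicine_rr: float = 0.80

    @classmethod
    def from_parameters(cls, params, statin_effect_multiplier: float = 1.0) -> "EffectInputs":
        return cls(
            baseline_ldl_mmol=params.baseline_ldl_mmol,
            pct_reduction=dict(params.ldl_pct_reduction),
            rr_per_mmol=dict(params.rr_per_mmol),
            statin_effect_multiplier=statin_effect_multiplier,
            colchicine_rr=params.colchicine_rr,
        )


def ldl_delta(dose_from: int, dose_to: int, inputs: EffectInputs) -> float:
    """Absolute LDL reduction (mmol/L) achieved by a dose change."""
    if dose_from not in STATIN_DOSES or dose_to not in STATIN_DOSES:
        raise ConfigurationError(f"doses must be in {STATIN_DOSES}: {dose_from}->{dose_to}")
    if dose_to < dose_from:
        raise ConfigurationError(f"statin de-escalation is not modelled: {dose_from}->{dose_to}")
    pct = lambda d: inputs.pct_reduction.get(d, 0.0) if d else 0.0
    return inputs.baseline_ldl_mmol * (pct(dose_to) - pct(dose_from))


def relative_risk_from_ldl(delta_ldl: float, rr_1mmol: float,
                           multiplier: float = 1.0) -> float:
    """RR = rr_1mmol ** delta_ldl, with the risk *reduction* rescaled by
    ``multiplier`` (1 - m x (1 - RR)); halving a relative risk directly would
    overstate efficacy for RR < 0.5."""
    if rr_1mmol <= 0:
        raise ConfigurationError(f"per-mmol RR must be positive, got {rr_1mmol}")
    if delta_ldl < 0:
        raise ConfigurationError(f"LDL reduction must be >= 0, got {delta_ldl}")
    rr = rr_1mmol ** delta_ldl
    return 1.0 - multiplier * (1.0 - rr)


def apply_colchicine(rr_statin: float, colchicine_rr: float, enabled: bool) -> float:
    """Multiply in the colchicine effect (an additional proportional MACE
    reduction beyond statins) when enabled."""
    if not 0.0 < rr_statin <= 1.0 or not 0.0 < colchicine_rr <= 1.0:
        raise ConfigurationError(
            f"relative risks must be in (0, 1]: statin {rr_statin}, colchicine {colchicine_rr}"
        )
    return rr_statin * colchicine_rr if enabled else rr_statin


def mace_relative_risks(treatment: TreatmentState, stratum: Stratum,
                        inputs: EffectInputs) -> dict:
    """Per-outcome relative risks for one treatment state in one stratum."""
    delta = ldl_delta(treatment.dose_from_mg, treatment.dose_to_mg, inputs)
    band = stratum.risk_band.value
    out = {}
    for outcome in MACE_STATES:
        rr1 = inputs.rr_per_mmol.get((outcome.value, band), 1.0)
        rr = relative_risk_from_ldl(delta, rr1, inputs.statin_effect_multiplier)
        out[outcome.value] = apply_colchicine(rr, inputs.colchicine_rr, treatment.colchicine)
    return out
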