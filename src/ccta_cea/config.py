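"""Model settings, the parameter schema, validation, and (de)serialisation.

Single source of truth for every quantity the model consumes: run settings
(:class:`ModelConfig`), the full parameter set (:class:`ParameterSet`), and
the probabilistic-sensitivity-analysis sampling specification
(:class:`DistributionSpec`). Configuration files are versioned YAML; all
currency is GBP, all rates are annual unless the field name says per-cycle.
"""
from __future__ import annotations

import copy
import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import yaml

from .errors import ConfigurationError
from .states import (
    ALL_STRATA,
    ABSORBING_STATES,
    Action,
    HealthState,
    MACE_STATES,
    RiskBand,
    STATIN_DOSES,
    Stratum,
    states_for,
)

SCHEMA_VERSION = 1

_STATE_NAMES = {s.value for s in HealthState}
_ACTION_NAMES = {a.value for a in Action}
_SUM_TOL = 1e-9


@dataclass
class ModelConfig:
    """Run-level settings of the decision model.

    Defaults follow the published analysis set-up: 3-month cycles over a
    30-year horizon, 3.5%/year discounting of both costs and outcomes, an
    NHS and personal social services perspective, and a 1000-draw PSA.
    """

    cycle_length_months: int = 3
    horizon_years: int = 30
    discount_rate_annual: float = 0.035
    perspective: str = "NHS and personal social services"
    ai_price_gbp: float = 700.0
    wtp_thresholds_gbp: list = field(default_factory=lambda: list(range(0, 30001, 500)))
    n_simulated_patients: int = 5000
    n_psa_draws: int = 1000
    seed: int = 2024
    half_cycle_correction: bool = False
    #: "linear" (events/life-months x cycle length, the published rule) or
    #: "exponential" (p = 1 - exp(-rate x cycle)).
    rate_conversion: str = "linear"

    @property
    def n_cycles(self) -> int:
        return self.horizon_years * 12 // self.cycle_length_months

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_months / 12.0

    def discount_factors(self) -> np.ndarray:
        """Per-cycle discount factors; cycle-0 accruals are undiscounted."""
        t = np.arange(self.n_cycles)
        return (1.0 + self.discount_rate_annual) ** (-t * self.cycle_years)

    def validate(self) -> None:
        if self.cycle_length_months <= 0 or 12 % self.cycle_length_months != 0:
            raise ConfigurationError(
                f"cycle_length_months must divide 12, got {self.cycle_length_months}"
            )
        if not 0.0 <= self.discount_rate_annual < 1.0:
            raise ConfigurationError(
                f"discount_rate_annual must be in [0, 1), got {self.discount_rate_annual}"
            )
        if self.horizon_years <= 0 or (self.horizon_years * 12) % self.cycle_length_months:
            raise ConfigurationError(
                "horizon_years x 12 must be an integer number of cycles; "
                f"got horizon {self.horizon_years} y at {self.cycle_length_months}-month cycles"
            )
        if any(b <= a for a, b in zip(self.wtp_thresholds_gbp, self.wtp_thresholds_gbp[1:])):
            raise ConfigurationError("wtp_thresholds_gbp must be strictly increasing")
        if self.ai_price_gbp < 0:
            raise ConfigurationError(f"ai_price_gbp must be >= 0, got {self.ai_price_gbp}")
        if self.n_psa_draws <= 0 or self.n_simulated_patients <= 0:
            raise ConfigurationError("n_psa_draws and n_simulated_patients must be positive")
        if self.rate_conversion not in ("linear", "exponential"):
            raise ConfigurationError(f"unknown rate_conversion {self.rate_conversion!r}")


def _default_rr_per_mmol() -> dict:
    # 0.78 per mmol/L LDL lowering for every MACE outcome and risk band; a
    # documented, user-overridable default for the per-mmol effect size.
    return {
        (outcome.value, band.value): 0.78
        for outcome in MACE_STATES
        for band in RiskBand
    }


@dataclass
class ParameterSet:
    """Every model input apart from run settings.

    ``transition_probs`` maps stratum -> from-state -> to-state -> per-cycle
    probability; the residual in each row is the stay probability. Costs are
    GBP, utilities are QALY weights per year in [0, 1]. ``ai_management_change``
    holds, per stratum, the observed share of patients whose statin management
    changes when the AI risk report is available (initiate: 0->40 mg out of the
    dose-0 mass; intensify: 40->80 mg out of the dose-40 mass).
    """

    transition_probs: dict
    state_cost_gbp: dict
    event_cost_gbp: dict
    utility: dict
    statin_cost_gbp_per_cycle: dict
    colchicine_cost_gbp_per_cycle: float
    stratum_weights: dict
    baseline_management: dict
    ai_management_change: dict
    baseline_ldl_mmol: float = 3.7
    ldl_pct_reduction: dict = field(default_factory=lambda: {40: 0.48, 80: 0.53})
    rr_per_mmol: dict = field(default_factory=_default_rr_per_mmol)
    colchicine_rr: float = 0.80
    nice_baseline_management: dict | None = None
    ai_management_change_guideline: dict | None = None

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


@dataclass
class DistributionSpec:
    """PSA sampling specification for a single parameter.

    Families follow health-technology-assessment convention: beta for
    probabilities and utilities, gamma for costs, lognormal for relative
    risks; ``point_mass`` disables sampling for the target. Parameterised by
    mean and standard error.
    """

    family: str
    target: str
    mean: float
    se: float = 0.0

    _FAMILIES = ("beta", "gamma", "lognormal", "point_mass")

    def validate(self) -> None:
        if self.family not in self._FAMILIES:
            raise ConfigurationError(f"unknown PSA family {self.family!r} for {self.target}")
        if self.family != "point_mass" and self.se < 0:
            raise ConfigurationError(f"negative se for {self.target}")
        root = self.target.split(".", 1)[0]
        if self.family == "beta" and root not in (
            "transition_probs",
            "stratum_event_prob",
            "utility",
        ):
            raise ConfigurationError(f"beta is only valid for probabilities/utilities: {self.target}")
        if self.family == "gamma" and "cost" not in root:
            raise ConfigurationError(f"gamma is only valid for costs: {self.target}")
        if self.family == "lognormal" and root not in ("rr_per_mmol", "colchicine_rr"):
            raise ConfigurationError(f"lognormal is only valid for relative risks: {self.target}")

    def sample(self, rng: np.random.Generator) -> float:
        m, s = self.mean, self.se
        if self.family == "point_mass" or s == 0.0:
            return m
        if self.family == "beta":
            v = s * s
            if v >= m * (1.0 - m):
                raise ConfigurationError(
                    f"beta se too large for mean {m} at {self.target}"
                )
            common = m * (1.0 - m) / v - 1.0
            return float(rng.beta(m * common, (1.0 - m) * common))
        if self.family == "gamma":
            shape = (m / s) ** 2
            scale = s * s / m
            return float(rng.gamma(shape, scale))
        # lognormal, parameterised so the sampled mean and se match
        sigma2 = math.log(1.0 + (s / m) ** 2)
        mu = math.log(m) - sigma2 / 2.0
        return float(rng.lognormal(mu, math.sqrt(sigma2)))


# ---------------------------------------------------------------------------
# validation

def _check_distribution(dist: dict, keys: Iterable, label: str, out: list) -> None:
    for k, p in dist.items():
        if not 0.0 <= p <= 1.0 + _SUM_TOL:
            out.append(f"{label}[{k}] = {p} outside [0, 1]")
    extra = set(dist) - set(keys)
    if extra:
        out.append(f"{label} has unknown keys {sorted(map(str, extra))}")
    total = sum(dist.values())
    if abs(total - 1.0) > _SUM_TOL:
        out.append(f"{label} sums to {total}, expected 1")


def _check_management_maps(params: ParameterSet, baseline: dict, change: dict,
                           tag: str, out: list) -> None:
    for stratum, dist in baseline.items():
        _check_distribution(dist, STATIN_DOSES, f"{tag}baseline_management[{stratum}]", out)
    for stratum, acts in change.items():
        _check_distribution(acts, _ACTION_NAMES, f"{tag}ai_management_change[{stratum}]", out)
        doses = baseline.get(stratum, {})
        if acts.get(Action.INITIATE.value, 0.0) > doses.get(0, 0.0) + _SUM_TOL:
            out.append(
                f"{tag}ai_management_change[{stratum}]: initiate share "
                f"{acts[Action.INITIATE.value]} exceeds baseline dose-0 share {doses.get(0, 0.0)}"
            )
        if acts.get(Action.INTENSIFY.value, 0.0) > doses.get(40, 0.0) + _SUM_TOL:
            out.append(
                f"{tag}ai_management_change[{stratum}]: intensify share "
                f"{acts[Action.INTENSIFY.value]} exceeds baseline dose-40 share {doses.get(40, 0.0)}"
            )


def validate_parameters(params: ParameterSet) -> list[str]:
    """Return a list of invariant violations (empty means valid).

    Each violation names the offending field and value.
    """
    out: list[str] = []

    for stratum, rows in params.transition_probs.items():
        if not isinstance(stratum, Stratum):
            out.append(f"transition_probs key {stratum!r} is not a Stratum")
            continue
        valid = {s.value for s in states_for(stratum)}
        for frm, row in rows.items():
            if str(frm) not in valid:
                out.append(f"transition_probs[{stratum}] row {frm!r} not a state of this stratum")
                continue
            total = 0.0
            for to, p in row.items():
                if str(to) not in valid:
                    out.append(f"transition_probs[{stratum}][{frm}] target {to!r} invalid")
                if str(to) == str(frm):
                    out.append(f"transition_probs[{stratum}][{frm}] must not include itself")
                if not 0.0 <= p <= 1.0:
                    out.append(f"transition_probs[{stratum}][{frm}][{to}] = {p} outside [0, 1]")
                total += p
            if total > 1.0 + _SUM_TOL:
                out.append(
                    f"transition_probs[{stratum}][{frm}] row sums to {total} > 1"
                )

    for name, table in (("state_cost_gbp", params.state_cost_gbp),
                        ("event_cost_gbp", params.event_cost_gbp)):
        for state, c in table.items():
            if str(state) not in _STATE_NAMES:
                out.append(f"{name} key {state!r} is not a health state")
            if c < 0:
                out.append(f"{name}[{state}] = {c} is negative")

    for state, u in params.utility.items():
        if str(state) not in _STATE_NAMES:
            out.append(f"utility key {state!r} is not a health state")
        if not 0.0 <= u <= 1.0:
            out.append(f"utility[{state}] = {u} outside [0, 1]")

    for dose, c in params.statin_cost_gbp_per_cycle.items():
        if dose not in STATIN_DOSES:
            out.append(f"statin_cost_gbp_per_cycle key {dose!r} not in {STATIN_DOSES}")
        if c < 0:
            out.append(f"statin_cost_gbp_per_cycle[{dose}] = {c} is negative")
    if params.colchicine_cost_gbp_per_cycle < 0:
        out.append(
            f"colchicine_cost_gbp_per_cycle = {params.colchicine_cost_gbp_per_cycle} is negative"
        )

    if params.baseline_ldl_mmol <= 0:
        out.append(f"baseline_ldl_mmol = {params.baseline_ldl_mmol} must be positive")
    pr40 = params.ldl_pct_reduction.get(40)
    pr80 = params.ldl_pct_reduction.get(80)
    if pr40 is None or pr80 is None or not (0.0 < pr40 < pr80 < 1.0):
        out.append(
            f"ldl_pct_reduction must satisfy 0 < pct(40) < pct(80) < 1, got {params.ldl_pct_reduction}"
        )

    for key, rr in params.rr_per_mmol.items():
        if not 0.0 < rr <= 1.0:
            out.append(f"rr_per_mmol[{key}] = {rr} outside (0, 1]")
    if not 0.0 < params.colchicine_rr <= 1.0:
        out.append(f"colchicine_rr = {params.colchicine_rr} outside (0, 1]")

    _check_distribution(params.stratum_weights, ALL_STRATA, "stratum_weights", out)
    _check_management_maps(params, params.baseline_management,
                           params.ai_management_change, "", out)
    if params.nice_baseline_management is not None:
        guideline_change = params.ai_management_change_guideline or {}
        _check_management_maps(params, params.nice_baseline_management,
                               guideline_change, "nice_", out)
    return out


# ---------------------------------------------------------------------------
# parameter paths (used by the PSA and tornado analyses)

def _convert_key(d: dict, segment: str):
    """Map a path segment onto the key type actually used in ``d``."""
    if not d:
        raise KeyError(segment)
    probe = next(iter(d))
    if isinstance(probe, Stratum):
        return Stratum.parse(segment)
    if isinstance(probe, tuple):
        return tuple(segment.split(":"))
    if isinstance(probe, int):
        return int(segment)
    return segment


def _walk(params: ParameterSet, path: str):
    segments = path.split(".")
    obj: Any = params
    for i, seg in enumerate(segments[:-1]):
        obj = getattr(obj, seg) if dataclasses.is_dataclass(obj) else obj[_convert_key(obj, seg)]
    return obj, segments[-1]


def get_param(params: ParameterSet, path: str):
    """Read a parameter by dotted path, e.g. ``utility.stroke`` or
    ``transition_probs.obstructive:high.obstructive_cad.mi``.

    The virtual prefix ``stratum_event_prob.<stratum>.<event>`` reads the
    per-cycle event probability shared by every alive from-state of a stratum.
    """
    if path.startswith("stratum_event_prob."):
        _, skey, event = path.split(".")
        rows = params.transition_probs[Stratum.parse(skey)]
        values = {row[event] for row in rows.values() if event in row}
        if not values:
            raise KeyError(path)
        if len(values) > 1:
            raise ConfigurationError(f"{path}: per-state values differ, not a shared parameter")
        return values.pop()
    obj, last = _walk(params, path)
    return getattr(obj, last) if dataclasses.is_dataclass(obj) else obj[_convert_key(obj, last)]


def set_param(params: ParameterSet, path: str, value) -> None:
    """Write a parameter by dotted path (see :func:`get_param`)."""
    if path.startswith("stratum_event_prob."):
        _, skey, event = path.split(".")
        rows = params.transition_probs[Stratum.parse(skey)]
        hit = False
        for row in rows.values():
            if event in row:
                row[event] = value
                hit = True
        if not hit:
            raise KeyError(path)
        return
    obj, last = _walk(params, path)
    if dataclasses.is_dataclass(obj):
        setattr(obj, last, value)
    else:
        obj[_convert_key(obj, last)] = value


# ---------------------------------------------------------------------------
# YAML (de)serialisation

def _stringify(obj):
    if isinstance(obj, dict):
        out = {}
        for k, v in obj.items():
            if isinstance(k, Stratum):
                k = k.key
            elif isinstance(k, tuple):
                k = ":".join(str(p) for p in k)
            elif isinstance(k, HealthState):
                k = k.value
            out[str(k)] = _stringify(v)
        return out
    if isinstance(obj, float) and obj == int(obj) and abs(obj) < 1e15:
        return obj
    return obj


def _params_to_mapping(params: ParameterSet) -> dict:
    raw = {f.name: getattr(params, f.name) for f in dataclasses.fields(ParameterSet)}
    return {k: _stringify(v) for k, v in raw.items() if v is not None}


_STRATUM_KEYED = {
    "transition_probs",
    "stratum_weights",
    "baseline_management",
    "ai_management_change",
    "nice_baseline_management",
    "ai_management_change_guideline",
}
_DOSE_KEYED = {"statin_cost_gbp_per_cycle", "ldl_pct_reduction"}


def _params_from_mapping(mapping: dict, defaults: ParameterSet) -> ParameterSet:
    known = {f.name for f in dataclasses.fields(ParameterSet)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigurationError(f"unknown parameter fields: {sorted(unknown)}")
    values = {f.name: copy.deepcopy(getattr(defaults, f.name))
              for f in dataclasses.fields(ParameterSet)}
    for name, value in mapping.items():
        try:
            if name in _STRATUM_KEYED and value is not None:
                value = {Stratum.parse(k): copy.deepcopy(v) for k, v in value.items()}
                if name in ("baseline_management", "nice_baseline_management"):
                    value = {s: {int(d): p for d, p in dist.items()} for s, dist in value.items()}
            elif name in _DOSE_KEYED:
                value = {int(k): v for k, v in value.items()}
            elif name == "rr_per_mmol":
                value = {tuple(k.split(":")): v for k, v in value.items()}
        except (TypeError, ValueError, AttributeError) as exc:
            raise ConfigurationError(f"parameter field {name!r} is malformed: {exc}") from exc
        values[name] = value
    try:
        return ParameterSet(**values)
    except TypeError as exc:  # pragma: no cover - guarded by `known` check
        raise ConfigurationError(str(exc)) from exc


def _config_from_mapping(mapping: dict) -> ModelConfig:
    known = {f.name: f.type for f in dataclasses.fields(ModelConfig)}
    unknown = set(mapping) - set(known)
    if unknown:
        raise ConfigurationError(f"unknown model settings: {sorted(unknown)}")
    cfg = ModelConfig()
    for name, value in mapping.items():
        current = getattr(cfg, name)
        if isinstance(current, bool):
            if not isinstance(value, bool):
                raise ConfigurationError(f"model.{name} must be a boolean, got {value!r}")
        elif isinstance(current, int) and not isinstance(value, int):
            raise ConfigurationError(f"model.{name} must be an integer, got {value!r}")
        elif isinstance(current, float) and not isinstance(value, (int, float)):
            raise ConfigurationError(f"model.{name} must be a number, got {value!r}")
        elif isinstance(current, list) and not isinstance(value, list):
            raise ConfigurationError(f"model.{name} must be a list, got {value!r}")
        setattr(cfg, name, value)
    cfg.validate()
    return cfg


def save_config(path, config: ModelConfig, params: ParameterSet,
                specs: list[DistributionSpec] | None = None) -> None:
    """Write the full configuration (settings, parameters, PSA specs) as YAML."""
    doc = {
        "schema": SCHEMA_VERSION,
        "model": dataclasses.asdict(config),
        "parameters": _params_to_mapping(params),
        "psa": [dataclasses.asdict(s) for s in (specs or [])],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True, default_flow_style=False))


def load_config(path) -> tuple[ModelConfig, ParameterSet, list[DistributionSpec]]:
    """Load a configuration file, filling documented defaults.

    Any parameter field omitted from the file falls back to the package's
    illustrative default parameter set; unknown keys are rejected.
    """
    from .defaults import default_parameters  # local import to avoid a cycle

    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"configuration file not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path} is not a mapping")
    unknown = set(doc) - {"schema", "model", "parameters", "psa"}
    if unknown:
        raise ConfigurationError(f"unknown top-level sections: {sorted(unknown)}")
    if "schema" not in doc:
        raise ConfigurationError("missing mandatory field: schema")
    if doc["schema"] != SCHEMA_VERSION:
        raise ConfigurationError(f"unsupported schema version {doc['schema']!r}")

    config = _config_from_mapping(doc.get("model") or {})
    params = _params_from_mapping(doc.get("parameters") or {}, default_parameters())
    violations = validate_parameters(params)
    if violations:
        raise ConfigurationError("invalid parameters:\n  " + "\n  ".join(violations))

    specs = []
    for entry in doc.get("psa") or []:
        try:
            spec = DistributionSpec(**entry)
        except TypeError as exc:
            raise ConfigurationError(f"malformed PSA entry {entry!r}: {exc}") from exc
        spec.validate()
        specs.append(spec)
    return config, params, specs
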