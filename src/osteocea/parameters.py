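"""Model input parameters: point estimates, uncertainty intervals and settings.

Every number the model consumes lives here as a typed, validated default, so a
run with :func:`default_parameters` is fully specified by the published input
set (Taiwan NHIRD fracture rates, hazard ratios, mortality, costs in 2020 USD,
and EQ-5D utilities).  Overrides come in through a flat YAML document via
:func:`load_parameters`; unspecified keys keep their defaults.

Age-banded quantities are stored as ``{band_lower_bound: value}`` mappings with
closed-open bands: an age belongs to the band whose lower bound is the largest
one not exceeding it, and ages above the top band use the top band.
"""

from __future__ import annotations

import copy
import io
import os
from dataclasses import dataclass, field, fields, is_dataclass
from typing import Any, Mapping

import yaml

__all__ = [
    "FRACTURE_TYPES",
    "Estimate",
    "FractureEffect",
    "BaselineRates",
    "MortalityTable",
    "CostTable",
    "UtilityTable",
    "SimulationSettings",
    "ModelParameters",
    "ParameterError",
    "age_band_lookup",
    "default_parameters",
    "load_parameters",
]

#: Fracture sites tracked by the model, ordered from most to least severe.
FRACTURE_TYPES = ("hip", "vertebral", "other")

TREATMENT = "treatment"
OFF_TREATMENT = "off-treatment"
ARMS = (TREATMENT, OFF_TREATMENT)


class ParameterError(ValueError):
    """A parameter violated its domain constraint.

    Carries the offending key path and the constraint that failed, so config
    errors point at the exact input.
    """

    def __init__(self, key: str, constraint: str):
        self.key = key
        self.constraint = constraint
        super().__init__(f"parameter '{key}': {constraint}")


@dataclass(frozen=True)
class Estimate:
    """A point estimate with an optional 95% confidence interval."""

    value: float
    ci_low: float | None = None
    ci_high: float | None = None

    def validate(self, key: str, *, positive: bool = False,
                 unit_interval: bool = False) -> None:
        if positive and not self.value > 0:
            raise ParameterError(key, "must be > 0")
        if unit_interval and not 0 < self.value <= 1:
            raise ParameterError(key, "must be in (0, 1]")
        if self.value < 0:
            raise ParameterError(key, "must be >= 0")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ParameterError(key, "CI bounds must be given together")
        if self.ci_low is not None and self.ci_high is not None:
            if not self.ci_low <= self.value <= self.ci_high:
                raise ParameterError(key, "must satisfy ci_low <= value <= ci_high")
            if positive and self.ci_low <= 0:
                raise ParameterError(key, "CI must be > 0")


def age_band_lookup(age: float, table: Mapping[int, float]) -> float:
    """Value of the closed-open age band containing ``age``.

    Ages above the top band fall into the top band; an age below the lowest
    band is an error (the model never produces one).
    """
    bounds = sorted(table)
    if age < bounds[0]:
        raise ParameterError("age", f"age {age} below lowest band start {bounds[0]}")
    chosen = bounds[0]
    for b in bounds:
        if age >= b:
            chosen = b
    return table[chosen]


@dataclass(frozen=True)
class FractureEffect:
    """Fracture hazard ratios, on-treatment versus off-treatment.

    The nonvertebral hazard ratio stands in for "other" (wrist / distal
    forearm) fractures, as in prior denosumab models.
    """

    hr_hip: Estimate
    hr_vertebral: Estimate
    hr_nonvertebral: Estimate

    def hazard_ratio(self, fracture_type: str) -> float:
        return {
            "hip": self.hr_hip,
            "vertebral": self.hr_vertebral,
            "other": self.hr_nonvertebral,
        }[fracture_type].value

    def validate(self) -> None:
        self.hr_hip.validate("effect.hr_hip", positive=True)
        self.hr_vertebral.validate("effect.hr_vertebral", positive=True)
        self.hr_nonvertebral.validate("effect.hr_nonvertebral", positive=True)


@dataclass(frozen=True)
class BaselineRates:
    """Annual fracture rates (events per patient-year) in untreated patients."""

    hip: Estimate
    vertebral: Estimate
    other: Estimate

    def rate(self, fracture_type: str) -> float:
        return getattr(self, fracture_type).value

    def validate(self) -> None:
        for name in ("hip", "vertebral", "other"):
            est: Estimate = getattr(self, name)
            est.validate(f"rates.{name}")
            if est.value < 0:
                raise ParameterError(f"rates.{name}", "must be >= 0")


@dataclass(frozen=True)
class MortalityTable:
    """Background mortality and post-fracture relative risks of death.

    ``well_annual`` maps age-band lower bounds to annual probabilities of
    death in the well state.  Relative risks apply in the first year after any
    fracture, and in subsequent years after hip and vertebral fracture, within
    a fracture-type-specific excess-mortality window (``excess_duration_years``).
    """

    well_annual: dict[int, float]
    rr_first_year: dict[str, dict[int, float]]
    rr_subsequent: dict[str, dict[int, float]]
    excess_duration_years: dict[str, float]

    def validate(self) -> None:
        for band, p in self.well_annual.items():
            if not 0 <= p <= 1:
                raise ParameterError(f"mortality.well_annual.{band}",
                                     "must be a probability in [0, 1]")
        for f, tab in self.rr_first_year.items():
            for band, rr in tab.items():
                if not rr > 0:
                    raise ParameterError(f"mortality.rr_first_year.{f}.{band}",
                                         "must be > 0")
        for f, tab in self.rr_subsequent.items():
            for band, rr in tab.items():
                if not rr > 0:
                    raise ParameterError(f"mortality.rr_subsequent.{f}.{band}",
                                         "must be > 0")
        for f, years in self.excess_duration_years.items():
            if not years > 0:
                raise ParameterError(f"mortality.excess_duration_years.{f}",
                                     "must be > 0")
        for f in ("hip", "vertebral"):
            if self.excess_duration_years[f] < 1:
                raise ParameterError(f"mortality.excess_duration_years.{f}",
                                     "must be >= 1 year (first-year states exist)")


@dataclass(frozen=True)
class CostTable:
    """Healthcare costs in 2020 USD: fracture care and treatment delivery."""

    fracture_first_year: dict[str, dict[int, float]]
    fracture_subsequent_annual: dict[str, float]
    drug_annual: float
    visit_routine: float
    visit_nurse: float
    dxa_scan: float

    def validate(self) -> None:
        for f, tab in self.fracture_first_year.items():
            for band, c in tab.items():
                if c < 0:
                    raise ParameterError(f"costs.fracture_first_year.{f}.{band}",
                                         "must be >= 0")
        for f, c in self.fracture_subsequent_annual.items():
            if c < 0:
                raise ParameterError(f"costs.fracture_subsequent_annual.{f}",
                                     "must be >= 0")
        for name in ("drug_annual", "visit_routine", "visit_nurse", "dxa_scan"):
            if getattr(self, name) < 0:
                raise ParameterError(f"costs.{name}", "must be >= 0")


@dataclass(frozen=True)
class UtilityTable:
    """Well-state EQ-5D utilities by age band and post-fracture multipliers."""

    well_by_age: dict[int, float]
    multiplier_first_year: dict[str, Estimate]
    multiplier_subsequent: dict[str, Estimate]

    def validate(self) -> None:
        for band, u in self.well_by_age.items():
            if not 0 <= u <= 1:
                raise ParameterError(f"utilities.well_by_age.{band}",
                                     "must be in [0, 1]")
        for f, est in self.multiplier_first_year.items():
            est.validate(f"utilities.multiplier_first_year.{f}", unit_interval=True)
        for f, est in self.multiplier_subsequent.items():
            est.validate(f"utilities.multiplier_subsequent.{f}", unit_interval=True)


@dataclass(frozen=True)
class SimulationSettings:
    """Cohort, horizon, discounting, persistence and analysis settings."""

    start_age: float = 77.0
    cycle_length: float = 0.5
    max_age: float = 110.0
    discount_rate_costs: float = 0.03
    discount_rate_qalys: float = 0.03
    intended_treatment_years: float = 5.0
    annual_discontinuation_rate: float = 0.317
    offset_years: float = 2.0
    wtp_threshold: float = 30038.0
    psa_iterations: int = 1000
    rng_seed: int = 20211012

    def validate(self) -> None:
        if self.cycle_length <= 0:
            raise ParameterError("settings.cycle_length", "must be > 0")
        if self.max_age <= self.start_age:
            raise ParameterError("settings.max_age", "must exceed start_age")
        for name in ("discount_rate_costs", "discount_rate_qalys"):
            if getattr(self, name) < 0:
                raise ParameterError(f"settings.{name}", "must be >= 0")
        if self.annual_discontinuation_rate < 0:
            raise ParameterError("settings.annual_discontinuation_rate",
                                 "must be >= 0")
        for name in ("intended_treatment_years", "offset_years"):
            ratio = getattr(self, name) / self.cycle_length
            if abs(ratio - round(ratio)) > 1e-9:
                raise ParameterError(
                    f"settings.{name}",
                    "must be an integer number of model cycles")
        if self.psa_iterations < 1:
            raise ParameterError("settings.psa_iterations", "must be >= 1")
        if self.wtp_threshold < 0:
            raise ParameterError("settings.wtp_threshold", "must be >= 0")

    @property
    def n_cycles(self) -> int:
        return int(round((self.max_age - self.start_age) / self.cycle_length))

    @property
    def cycles_per_year(self) -> int:
        return int(round(1.0 / self.cycle_length))

    @property
    def treatment_cycles(self) -> int:
        return int(round(self.intended_treatment_years / self.cycle_length))

    @property
    def offset_cycles(self) -> int:
        return int(round(self.offset_years / self.cycle_length))


@dataclass(frozen=True)
class ModelParameters:
    """The complete, validated input set of the cost-effectiveness model."""

    effect: FractureEffect
    rates: BaselineRates
    mortality: MortalityTable
    costs: CostTable
    utilities: UtilityTable
    settings: SimulationSettings

    def validate(self) -> "ModelParameters":
        self.effect.validate()
        self.rates.validate()
        self.mortality.validate()
        self.costs.validate()
        self.utilities.validate()
        self.settings.validate()
        return self

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        """Plain nested-dict form (YAML/JSON friendly, used by config & PSA)."""
        return _to_plain(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelParameters":
        return _parameters_from_dict(data).validate()

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def replace_value(self, path: str, value: float) -> dict:
        """Return ``to_dict()`` with the scalar at dotted ``path`` replaced.

        Point-estimate leaves (those stored with CI bounds) are replaced as a
        bare scalar, which drops the printed CI — appropriate for sampled or
        user-overridden values.
        """
        d = self.to_dict()
        set_path(d, path, value)
        return d


def _to_plain(obj: Any) -> Any:
    if isinstance(obj, Estimate):
        if obj.ci_low is None:
            return obj.value
        return {"value": obj.value, "ci_low": obj.ci_low, "ci_high": obj.ci_high}
    if is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def _as_estimate(key: str, raw: Any) -> Estimate:
    if isinstance(raw, Estimate):
        return raw
    if isinstance(raw, Mapping):
        try:
            return Estimate(float(raw["value"]),
                            None if raw.get("ci_low") is None else float(raw["ci_low"]),
                            None if raw.get("ci_high") is None else float(raw["ci_high"]))
        except (KeyError, TypeError, ValueError):
            raise ParameterError(key, "expected {value, ci_low, ci_high} or a number")
    try:
        return Estimate(float(raw))
    except (TypeError, ValueError):
        raise ParameterError(key, "expected a number")


def _band_table(key: str, raw: Mapping) -> dict[int, float]:
    try:
        return {int(b): float(v) for b, v in raw.items()}
    except (TypeError, ValueError):
        raise ParameterError(key, "expected {age_band: number}")


def _parameters_from_dict(data: Mapping) -> ModelParameters:
    eff = data["effect"]
    effect = FractureEffect(
        _as_estimate("effect.hr_hip", eff["hr_hip"]),
        _as_estimate("effect.hr_vertebral", eff["hr_vertebral"]),
        _as_estimate("effect.hr_nonvertebral", eff["hr_nonvertebral"]),
    )
    r = data["rates"]
    rates = BaselineRates(
        _as_estimate("rates.hip", r["hip"]),
        _as_estimate("rates.vertebral", r["vertebral"]),
        _as_estimate("rates.other", r["other"]),
    )
    m = data["mortality"]
    mortality = MortalityTable(
        well_annual=_band_table("mortality.well_annual", m["well_annual"]),
        rr_first_year={f: _band_table(f"mortality.rr_first_year.{f}", t)
                       for f, t in m["rr_first_year"].items()},
        rr_subsequent={f: _band_table(f"mortality.rr_subsequent.{f}", t)
                       for f, t in m["rr_subsequent"].items()},
        excess_duration_years={f: float(v)
                               for f, v in m["excess_duration_years"].items()},
    )
    c = data["costs"]
    costs = CostTable(
        fracture_first_year={f: _band_table(f"costs.fracture_first_year.{f}", t)
                             for f, t in c["fracture_first_year"].items()},
        fracture_subsequent_annual={f: float(v)
                                    for f, v in c["fracture_subsequent_annual"].items()},
        drug_annual=float(c["drug_annual"]),
        visit_routine=float(c["visit_routine"]),
        visit_nurse=float(c["visit_nurse"]),
        dxa_scan=float(c["dxa_scan"]),
    )
    u = data["utilities"]
    utilities = UtilityTable(
        well_by_age=_band_table("utilities.well_by_age", u["well_by_age"]),
        multiplier_first_year={f: _as_estimate(f"utilities.multiplier_first_year.{f}", v)
                               for f, v in u["multiplier_first_year"].items()},
        multiplier_subsequent={f: _as_estimate(f"utilities.multiplier_subsequent.{f}", v)
                               for f, v in u["multiplier_subsequent"].items()},
    )
    s = data["settings"]
    settings = SimulationSettings(**{k: (int(v) if k in ("psa_iterations", "rng_seed")
                                         else float(v))
                                     for k, v in s.items()})
    return ModelParameters(effect, rates, mortality, costs, utilities, settings)


def default_parameters() -> ModelParameters:
    """The published base-case input set (all values as printed)."""
    effect = FractureEffect(
        hr_hip=Estimate(0.62, 0.52, 0.75),
        hr_vertebral=Estimate(0.63, 0.52, 0.75),
        hr_nonvertebral=Estimate(0.62, 0.53, 0.73),
    )
    rates = BaselineRates(
        hip=Estimate(0.017, 0.016, 0.019),
        vertebral=Estimate(0.017, 0.015, 0.018),
        other=Estimate(0.004, 0.003, 0.005),
    )
    mortality = MortalityTable(
        well_annual={70: 0.041, 80: 0.089, 90: 0.168},
        rr_first_year={
            "hip": {70: 1.57, 80: 1.46, 90: 1.5},
            "vertebral": {70: 1.26, 80: 1.18, 90: 1.15},
            "other": {70: 0.97, 80: 1.01, 90: 1.72},
        },
        rr_subsequent={
            "hip": {70: 1.69, 80: 1.37, 90: 1.12},
            "vertebral": {70: 1.27, 80: 1.00, 90: 1.15},
        },
        excess_duration_years={"hip": 8.0, "vertebral": 8.0, "other": 1.0},
    )
    costs = CostTable(
        fracture_first_year={
            "hip": {70: 4315.0, 80: 4395.0, 90: 3930.0},
            "vertebral": {70: 1604.0, 80: 1844.0, 90: 1354.0},
            "other": {70: 1117.0, 80: 1571.0, 90: 1281.0},
        },
        fracture_subsequent_annual={"hip": 1163.0, "vertebral": 734.0},
        drug_annual=400.0,
        visit_routine=10.54,
        visit_nurse=12.04,
        dxa_scan=20.01,
    )
    utilities = UtilityTable(
        well_by_age={75: 0.669, 80: 0.655, 85: 0.643},
        multiplier_first_year={
            "hip": Estimate(0.55, 0.53, 0.57),
            "vertebral": Estimate(0.68, 0.65, 0.70),
            "other": Estimate(0.83, 0.82, 0.84),
        },
        multiplier_subsequent={
            "hip": Estimate(0.86, 0.84, 0.89),
            "vertebral": Estimate(0.85, 0.82, 0.87),
        },
    )
    return ModelParameters(effect, rates, mortality, costs, utilities,
                           SimulationSettings()).validate()


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict) \
                and "value" not in out[k]:
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v) if isinstance(v, Mapping) else v
    return out


def load_parameters(config_source: Any = None) -> ModelParameters:
    """Load parameters from a YAML document merged over the defaults.

    ``config_source`` may be a path, a YAML string, an open file, a mapping,
    or ``None`` (pure defaults).  A bare number for a point-estimate key
    replaces the value and drops the printed CI; out-of-range values raise
    :class:`ParameterError` naming the key.
    """
    if config_source is None:
        return default_parameters()
    if isinstance(config_source, Mapping):
        override: Mapping = config_source
    else:
        if isinstance(config_source, (str, os.PathLike)) \
                and os.path.exists(os.fspath(config_source)):
            with open(config_source, "r") as fh:
                text = fh.read()
        elif isinstance(config_source, io.IOBase) or hasattr(config_source, "read"):
            text = config_source.read()
        else:
            text = str(config_source)
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ParameterError("<config>", "top level must be a mapping")
        override = loaded
    merged = _deep_merge(default_parameters().to_dict(), override)
    return ModelParameters.from_dict(merged)


# -- dotted-path access (config tooling and PSA sampling) ------------------

def get_path(data: Mapping, path: str) -> Any:
    """Fetch a (possibly Estimate-shaped) leaf from a parameter dict."""
    node: Any = data
    for part in path.split("."):
        if isinstance(node, Mapping) and part not in node:
            # age-band keys are ints in the dict form
            try:
                node = node[int(part)]
                continue
            except (KeyError, ValueError):
                raise KeyError(f"no parameter at path '{path}'")
        node = node[part]
    if isinstance(node, Mapping) and "value" in node:
        return node["value"]
    return node


def set_path(data: dict, path: str, value: float) -> None:
    """Set a scalar leaf in a parameter dict, collapsing any CI annotation."""
    parts = path.split(".")
    node: Any = data
    for part in parts[:-1]:
        if part not in node:
            try:
                node = node[int(part)]
                continue
            except (KeyError, ValueError):
                raise KeyError(f"no parameter at path '{path}'")
        else:
            node = node[part]
    last = parts[-1]
    if last not in node:
        try:
            int_key = int(last)
        except ValueError:
            raise KeyError(f"no parameter at path '{path}'")
        if int_key not in node:
            raise KeyError(f"no parameter at path '{path}'")
        node[int_key] = float(value)
        return
    node[last] = float(value)
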