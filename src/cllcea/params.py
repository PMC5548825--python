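"""Parameter schema, validation and config I/O.

Every scalar the decision model consumes is a :class:`Parameter`: per-cycle
transition probabilities, per-cycle state costs, one-off costs, utility
weights, rates and proportions.  A :class:`ParameterSet` bundles the
parameters with the run settings (discount rate, cycle length, horizon,
cohort size, starting age, PSA coefficient of variation, willingness-to-pay
thresholds).

Config files are YAML (``schema_version: 1``) with two top-level mappings,
``settings`` and ``parameters``.  Unknown keys are rejected, every invariant
is checked on load, and a set loaded for the full five-strategy comparison is
additionally checked for completeness (every parameter name referenced by any
strategy's state space must resolve).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import TYPE_CHECKING, Iterable, Mapping

import yaml

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .societal import SocietalCostSpec

__all__ = [
    "Parameter",
    "ParameterSet",
    "ParameterError",
    "load_parameter_set",
    "write_parameter_set",
    "resolve",
]

ROLES = (
    "transition-probability",
    "state-cost",
    "one-off-cost",
    "utility",
    "rate",
    "proportion",
    "societal-cost",
)
DISTRIBUTIONS = ("beta", "gamma", "fixed")
#: roles drawn from a beta distribution in the PSA (bounded on [0, 1])
BETA_ROLES = ("transition-probability", "utility", "proportion")
#: roles drawn from a gamma distribution in the PSA (nonnegative, unbounded)
GAMMA_ROLES = ("state-cost", "one-off-cost", "rate", "societal-cost")
VARIANCE_SOURCES = ("reported", "cv-default")

SCHEMA_VERSION = 1

_SETTINGS_FIELDS = (
    "discount_rate_annual",
    "cycle_length_days",
    "horizon_years",
    "cohort_size",
    "starting_age_years",
    "cv_default",
    "thresholds_gbp",
    "utility_mode",
    "half_cycle",
)

UTILITY_MODES = ("adjusted", "complication-adjusted")
HALF_CYCLE_MODES = ("both", "costs", "outcomes", "none")


class ParameterError(ValueError):
    """A parameter or parameter set violates the schema."""


@dataclass(frozen=True)
class Parameter:
    """A single model input with its base value, range and PSA distribution.

    ``low``/``high`` bound the univariate sensitivity range (default +/-50%
    of the base value, truncated to the role's domain); ``distribution``
    names the PSA family: beta for probabilities, proportions and utilities,
    gamma for costs and rates, ``fixed`` for quantities never sampled.
    """

    name: str
    role: str
    value: float
    low: float
    high: float
    distribution: str = "fixed"
    variance_source: str = "cv-default"

    def validate(self) -> None:
        p = self
        if not p.name or not isinstance(p.name, str):
            raise ParameterError(f"parameter has an invalid name: {p.name!r}")
        if p.role not in ROLES:
            raise ParameterError(f"{p.name}: unknown role {p.role!r}")
        if p.distribution not in DISTRIBUTIONS:
            raise ParameterError(
                f"{p.name}: unknown distribution {p.distribution!r}"
            )
        if p.variance_source not in VARIANCE_SOURCES:
            raise ParameterError(
                f"{p.name}: unknown variance_source {p.variance_source!r}"
            )
        if p.distribution == "beta" and p.role not in BETA_ROLES:
            raise ParameterError(
                f"{p.name}: beta distribution is reserved for probabilities, "
                f"proportions and utilities, not role {p.role!r}"
            )
        if p.distribution == "gamma" and p.role not in GAMMA_ROLES:
            raise ParameterError(
                f"{p.name}: gamma distribution is reserved for costs and "
                f"rates, not role {p.role!r}"
            )
        for bound_name, v in (("value", p.value), ("low", p.low), ("high", p.high)):
            if not _is_finite_number(v):
                raise ParameterError(f"{p.name}: {bound_name} is not a finite number")
        if not (p.low <= p.value <= p.high):
            raise ParameterError(
                f"{p.name}: requires low <= value <= high, got "
                f"{p.low} / {p.value} / {p.high}"
            )
        if p.role in ("transition-probability", "proportion", "utility"):
            if not (0.0 <= p.low and p.high <= 1.0):
                raise ParameterError(
                    f"{p.name}: {p.role} values must lie in [0, 1], got "
                    f"[{p.low}, {p.high}]"
                )
        else:  # costs and rates are nonnegative
            if p.low < 0.0:
                raise ParameterError(f"{p.name}: {p.role} must be >= 0")

    def replace_value(self, value: float) -> "Parameter":
        """New parameter with ``value`` substituted (range widened to admit it)."""
        low = min(self.low, value)
        high = max(self.high, value)
        return dataclasses.replace(self, value=value, low=low, high=high)


def _is_finite_number(x) -> bool:
    return isinstance(x, (int, float)) and x == x and abs(x) != float("inf")


@dataclass(frozen=True)
class ParameterSet:
    """All model inputs plus run settings.

    ``societal`` optionally carries the societal-perspective cost
    specification attached by :func:`cllcea.societal.apply_societal`; it is a
    runtime annotation, not part of the serialised config.
    """

    parameters: Mapping[str, Parameter]
    discount_rate_annual: float = 0.035
    cycle_length_days: int = 28
    horizon_years: float = 30.0
    cohort_size: int = 10_000
    starting_age_years: float = 65.0
    cv_default: float = 0.10
    thresholds_gbp: tuple[float, ...] = (20_000.0, 30_000.0, 50_000.0)
    utility_mode: str = "adjusted"
    half_cycle: str = "both"
    societal: "SocietalCostSpec | None" = None

    def __post_init__(self):
        object.__setattr__(
            self, "parameters", MappingProxyType(dict(self.parameters))
        )
        object.__setattr__(self, "thresholds_gbp", tuple(self.thresholds_gbp))

    # -- access -----------------------------------------------------------
    def value(self, name: str) -> float:
        try:
            return self.parameters[name].value
        except KeyError:
            raise ParameterError(f"unresolved parameter {name!r}") from None

    def values(self, names: Iterable[str]) -> float:
        return sum(self.value(n) for n in names)

    def __contains__(self, name: str) -> bool:
        return name in self.parameters

    @property
    def cycle_years(self) -> float:
        """Length of one model cycle in years (28/365.25 in the base case)."""
        return self.cycle_length_days / 365.25

    @property
    def n_cycles(self) -> int:
        """Whole propagation steps over the horizon (391 in the base case)."""
        return int(self.horizon_years * 365.25 // self.cycle_length_days)

    # -- validation -------------------------------------------------------
    def validate(self, complete: bool = False) -> None:
        if self.discount_rate_annual < 0:
            raise ParameterError("discount_rate_annual must be >= 0")
        if self.cycle_length_days <= 0:
            raise ParameterError("cycle_length_days must be > 0")
        if self.horizon_years <= 0:
            raise ParameterError("horizon_years must be > 0")
        if self.cohort_size <= 0:
            raise ParameterError("cohort_size must be > 0")
        if self.starting_age_years < 0:
            raise ParameterError("starting_age_years must be >= 0")
        if not (0 <= self.cv_default < 1):
            raise ParameterError("cv_default must lie in [0, 1)")
        if any(t < 0 for t in self.thresholds_gbp):
            raise ParameterError("thresholds_gbp must be >= 0")
        if self.utility_mode not in UTILITY_MODES:
            raise ParameterError(f"unknown utility_mode {self.utility_mode!r}")
        if self.half_cycle not in HALF_CYCLE_MODES:
            raise ParameterError(f"unknown half_cycle mode {self.half_cycle!r}")
        for name, p in self.parameters.items():
            if name != p.name:
                raise ParameterError(
                    f"parameter key {name!r} does not match its name {p.name!r}"
                )
            p.validate()
        if complete:
            missing = self.missing_names()
            if missing:
                raise ParameterError(
                    "parameter set does not cover the five strategies; "
                    "missing: " + ", ".join(sorted(missing))
                )

    def missing_names(self) -> set[str]:
        """Names referenced by any of the five strategies but absent here."""
        from .strategies import STRATEGY_NAMES, referenced_parameters

        needed: set[str] = set()
        for name in STRATEGY_NAMES:
            needed |= referenced_parameters(name)
        return {n for n in needed if n not in self.parameters}

    # -- transformation ---------------------------------------------------
    def resolve(self, overrides: Mapping[str, float]) -> "ParameterSet":
        """New set with ``overrides`` (name -> value) applied and re-validated."""
        params = dict(self.parameters)
        for name, value in overrides.items():
            if name not in params:
                raise ParameterError(f"unknown override name {name!r}")
            params[name] = params[name].replace_value(float(value))
        out = dataclasses.replace(self, parameters=params)
        out.validate()
        return out

    def with_settings(self, **settings) -> "ParameterSet":
        """New set with run settings replaced (e.g. ``horizon_years=10``)."""
        for key in settings:
            if key not in _SETTINGS_FIELDS:
                raise ParameterError(f"unknown setting {key!r}")
        out = dataclasses.replace(self, **settings)
        out.validate()
        return out

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "settings": {
                "discount_rate_annual": self.discount_rate_annual,
                "cycle_length_days": self.cycle_length_days,
                "horizon_years": self.horizon_years,
                "cohort_size": self.cohort_size,
                "starting_age_years": self.starting_age_years,
                "cv_default": self.cv_default,
                "thresholds_gbp": list(self.thresholds_gbp),
                "utility_mode": self.utility_mode,
                "half_cycle": self.half_cycle,
            },
            "parameters": {
                name: {
                    "role": p.role,
                    "value": p.value,
                    "low": p.low,
                    "high": p.high,
                    "distribution": p.distribution,
                    "variance_source": p.variance_source,
                }
                for name, p in sorted(self.parameters.items())
            },
        }

    @classmethod
    def from_dict(cls, data: dict, complete: bool = True) -> "ParameterSet":
        if not isinstance(data, dict):
            raise ParameterError("config root must be a mapping")
        unknown = set(data) - {"schema_version", "settings", "parameters"}
        if unknown:
            raise ParameterError(f"unknown top-level keys: {sorted(unknown)}")
        if data.get("schema_version") != SCHEMA_VERSION:
            raise ParameterError(
                f"unsupported schema_version {data.get('schema_version')!r}; "
                f"expected {SCHEMA_VERSION}"
            )
        settings = dict(data.get("settings") or {})
        unknown = set(settings) - set(_SETTINGS_FIELDS)
        if unknown:
            raise ParameterError(f"unknown settings keys: {sorted(unknown)}")
        raw_params = data.get("parameters")
        if not isinstance(raw_params, dict) or not raw_params:
            raise ParameterError("config must define a non-empty parameters map")
        params: dict[str, Parameter] = {}
        for name, spec in raw_params.items():
            if not isinstance(spec, dict):
                raise ParameterError(f"{name}: parameter entry must be a mapping")
            unknown = set(spec) - {
                "role", "value", "low", "high", "distribution", "variance_source",
            }
            if unknown:
                raise ParameterError(f"{name}: unknown fields {sorted(unknown)}")
            for required in ("role", "value"):
                if required not in spec:
                    raise ParameterError(f"{name}: missing required key {required!r}")
            value = float(spec["value"])
            params[name] = Parameter(
                name=name,
                role=spec["role"],
                value=value,
                low=float(spec.get("low", value)),
                high=float(spec.get("high", value)),
                distribution=spec.get("distribution", "fixed"),
                variance_source=spec.get("variance_source", "cv-default"),
            )
        if "thresholds_gbp" in settings:
            settings["thresholds_gbp"] = tuple(
                float(t) for t in settings["thresholds_gbp"]
            )
        ps = cls(parameters=params, **settings)
        ps.validate(complete=complete)
        return ps


def load_parameter_set(path: str | Path, complete: bool = True) -> ParameterSet:
    """Read and validate a parameter config file.

    ``complete=True`` (the default) additionally requires the set to resolve
    every name referenced by the five wired strategies; pass ``False`` for
    partial sets used in isolation.
    """
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParameterError(f"could not parse {path}: {exc}") from exc
    return ParameterSet.from_dict(data, complete=complete)


def write_parameter_set(ps: ParameterSet, path: str | Path) -> None:
    """Serialise ``ps`` so that ``load(write(ps)) == ps`` (societal annotation
    excluded; it is runtime-only)."""
    Path(path).write_text(
        yaml.safe_dump(ps.to_dict(), sort_keys=False, default_flow_style=False)
    )


def resolve(ps: ParameterSet, overrides: Mapping[str, float]) -> ParameterSet:
    """Functional alias for :meth:`ParameterSet.resolve`."""
    return ps.resolve(overrides)
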