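"""Model inputs: named parameters, uncertainty distributions, config I/O.

Every quantity the decision model consumes is a named :class:`ParameterSpec`
carrying a base value, a distribution family (``beta`` for probabilities and
utilities, ``gamma`` for costs, ``point`` for fixed structural values) and a
dispersion (standard error on the same scale as the value).  The built-in
base case is the published US-payer input set for staging colorectal liver
metastases (CRLM) at a mean age of 68, three imaging strategies (CE-CT, MRI
with liver-specific contrast, 18F-FDG PET/CT), a 3% annual discount rate and
a willingness-to-pay of $100,000/QALY.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import yaml
from scipy import stats

__all__ = [
    "ParameterError",
    "ParameterSpec",
    "StrategySpec",
    "ParameterTable",
    "builtin_basecase",
    "make_distribution",
    "load_parameter_table",
    "write_parameter_table",
    "load_overrides",
    "export_csv",
    "default_dispersion",
    "REQUIRED_PARAMETERS",
    "STRUCTURAL_DEFAULTS",
]

DIST_FAMILIES = ("beta", "gamma", "point")

#: Parameters every valid table must define (on top of the per-strategy
#: sensitivity/specificity/imaging-cost triples).
REQUIRED_PARAMETERS = (
    "overall_resection_cost",
    "delayed_resection_cost",
    "annual_crlm_cost",
    "u_tumor_free",
    "u_post_resection",
    "u_recurrence",
    "u_undetected",
    "p_metastases",
    "p_treatment_success",
    "p_recurrence_5y",
    "p_death_untreated",
)

#: Structural knobs with defaults, injected when a config omits them.
#: ``p_detect``      annual probability an occult (false-negative) tumour is
#:                   clinically detected; 1.0 = found at the next annual review.
#: ``fp_workup_cost`` one-time cost charged to false positives at t=0.
#: ``undetected_annual_cost`` yearly cost while metastases remain undetected.
#: ``p_death_recurrence`` annual tumour mortality in the recurrence state
#:                   (defaults to the untreated-disease mortality).
STRUCTURAL_DEFAULTS = {
    "p_detect": ("beta", 1.0, 0.0),
    "fp_workup_cost": ("gamma", 964.00, 0.0),
    "undetected_annual_cost": ("gamma", 0.0, 0.0),
    "p_death_recurrence": ("beta", 0.2417, 0.0),
}

REQUIRED_SETTINGS = ("discount_rate", "wtp", "horizon", "cycle_length", "start_age")

_BETA_CAP = 0.9  # dispersion cap as a fraction of sqrt(m(1-m)), keeps moments feasible


class ParameterError(ValueError):
    """Invalid or missing model input; the message names the offender."""


def default_dispersion(base_value: float, dist_family: str, frac: float = 0.20) -> float:
    """Default standard error: ``frac`` of the base value, capped for beta
    parameters so that the method-of-moments fit stays feasible."""
    if dist_family == "point":
        return 0.0
    s = frac * base_value
    if dist_family == "beta":
        if base_value <= 0.0 or base_value >= 1.0:
            return 0.0
        s = min(s, _BETA_CAP * math.sqrt(base_value * (1.0 - base_value)))
    return s


@dataclass(frozen=True)
class ParameterSpec:
    """One named model input with its uncertainty annotation."""

    name: str
    base_value: float
    dist_family: str = "point"
    dispersion: float = 0.0

    def __post_init__(self) -> None:
        if self.dist_family not in DIST_FAMILIES:
            raise ParameterError(
                f"{self.name}: unknown distribution family {self.dist_family!r}"
            )
        if self.dispersion < 0:
            raise ParameterError(f"{self.name}: dispersion must be >= 0")
        if self.dist_family == "beta" and not 0.0 <= self.base_value <= 1.0:
            raise ParameterError(
                f"{self.name}: beta-family value {self.base_value} outside [0, 1]"
            )
        if self.dist_family == "gamma" and self.base_value < 0.0:
            raise ParameterError(
                f"{self.name}: gamma-family value {self.base_value} must be >= 0"
            )

    @property
    def sampled(self) -> bool:
        return self.dispersion > 0.0 and self.dist_family != "point"


@dataclass(frozen=True)
class StrategySpec:
    """One imaging strategy: diagnostic accuracy and the upfront scan tariff."""

    name: str
    sensitivity: float
    specificity: float
    imaging_cost: float

    def __post_init__(self) -> None:
        for label, p in (("sensitivity", self.sensitivity), ("specificity", self.specificity)):
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{self.name} {label} {p} outside [0, 1]")
        if self.imaging_cost < 0:
            raise ParameterError(f"{self.name} imaging cost must be >= 0")


class _PointMass:
    """Degenerate distribution returning the base value always."""

    def __init__(self, value: float):
        self._value = float(value)

    def mean(self) -> float:
        return self._value

    def rvs(self, size=None, random_state=None):
        import numpy as np

        if size is None:
            return self._value
        return np.full(size, self._value)


def make_distribution(spec: ParameterSpec):
    """Sampleable distribution for a parameter, mean-matched to its base value.

    Beta is parameterised by the method of moments,
    ``alpha = m*(m*(1-m)/s^2 - 1)``, ``beta = (1-m)*(m*(1-m)/s^2 - 1)``;
    gamma by ``k = (m/s)^2``, ``theta = s^2/m``.  Zero dispersion (or the
    ``point`` family) yields a point mass at the base value.
    """
    m, s = spec.base_value, spec.dispersion
    if spec.dist_family == "point" or s == 0.0:
        return _PointMass(m)
    if spec.dist_family == "beta":
        if m <= 0.0 or m >= 1.0:
            raise ParameterError(
                f"{spec.name}: beta mean {m} with dispersion > 0 is infeasible"
            )
        if s * s >= m * (1.0 - m):
            raise ParameterError(
                f"{spec.name}: beta dispersion {s} infeasible (s^2 >= m(1-m))"
            )
        nu = m * (1.0 - m) / (s * s) - 1.0
        return stats.beta(m * nu, (1.0 - m) * nu)
    if spec.dist_family == "gamma":
        if m <= 0.0:
            raise ParameterError(
                f"{spec.name}: gamma mean {m} with dispersion > 0 is infeasible"
            )
        return stats.gamma((m / s) ** 2, scale=s * s / m)
    raise ParameterError(f"{spec.name}: unknown family {spec.dist_family!r}")


@dataclass
class ParameterTable:
    """Ordered collection of parameters plus fixed run settings.

    Strategy-level inputs live in the table under the keys
    ``sens_<slug>``, ``spec_<slug>``, ``cost_<slug>`` so that deterministic
    and probabilistic sensitivity analyses can vary them like any other
    parameter; :meth:`strategy_specs` materialises :class:`StrategySpec`
    objects from the current values.
    """

    specs: dict[str, ParameterSpec]
    strategies: tuple[tuple[str, str], ...]  # (label, slug)
    discount_rate: float = 0.03
    wtp: float = 100_000.0
    horizon: int = 5
    cycle_length: float = 1.0
    start_age: float = 68.0
    recurrence_input: str = "cumulative_5y"  # or "annual"

    def __post_init__(self) -> None:
        self.validate()

    # -- access -----------------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self.specs[name].base_value

    def __contains__(self, name: str) -> bool:
        return name in self.specs

    def spec(self, name: str) -> ParameterSpec:
        return self.specs[name]

    def values(self) -> dict[str, float]:
        return {k: v.base_value for k, v in self.specs.items()}

    def sampled_specs(self) -> list[ParameterSpec]:
        return [s for s in self.specs.values() if s.sampled]

    def strategy_specs(self, values: Mapping[str, float] | None = None) -> list[StrategySpec]:
        vals = self.values() if values is None else values
        return [
            StrategySpec(label, vals[f"sens_{slug}"], vals[f"spec_{slug}"], vals[f"cost_{slug}"])
            for label, slug in self.strategies
        ]

    # -- editing ----------------------------------------------------------
    def replace_values(self, **updates: float) -> "ParameterTable":
        """New table with the given base values changed, all else equal."""
        specs = dict(self.specs)
        for name, value in updates.items():
            if name not in specs:
                raise ParameterError(f"unknown parameter {name!r}")
            specs[name] = replace(specs[name], base_value=float(value))
        return ParameterTable(
            specs,
            self.strategies,
            self.discount_rate,
            self.wtp,
            self.horizon,
            self.cycle_length,
            self.start_age,
            self.recurrence_input,
        )

    def with_settings(self, **settings) -> "ParameterTable":
        kwargs = dict(
            discount_rate=self.discount_rate,
            wtp=self.wtp,
            horizon=self.horizon,
            cycle_length=self.cycle_length,
            start_age=self.start_age,
            recurrence_input=self.recurrence_input,
        )
        for key, val in settings.items():
            if key not in kwargs:
                raise ParameterError(f"unknown setting {key!r}")
            kwargs[key] = val
        return ParameterTable(dict(self.specs), self.strategies, **kwargs)

    def with_spec(self, spec: ParameterSpec) -> "ParameterTable":
        specs = dict(self.specs)
        specs[spec.name] = spec
        return ParameterTable(
            specs,
            self.strategies,
            self.discount_rate,
            self.wtp,
            self.horizon,
            self.cycle_length,
            self.start_age,
            self.recurrence_input,
        )

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.discount_rate < 0:
            raise ParameterError(f"discount_rate {self.discount_rate} must be >= 0")
        if int(self.horizon) != self.horizon or self.horizon < 1:
            raise ParameterError(f"horizon {self.horizon} must be an integer >= 1")
        self.horizon = int(self.horizon)
        if self.cycle_length <= 0:
            raise ParameterError(f"cycle_length {self.cycle_length} must be > 0")
        if self.wtp < 0:
            raise ParameterError(f"wtp {self.wtp} must be >= 0")
        if self.recurrence_input not in ("cumulative_5y", "annual"):
            raise ParameterError(
                f"recurrence_input {self.recurrence_input!r} must be "
                "'cumulative_5y' or 'annual'"
            )
        if not self.strategies:
            raise ParameterError("at least one strategy is required")
        required = list(REQUIRED_PARAMETERS)
        for _, slug in self.strategies:
            required += [f"sens_{slug}", f"spec_{slug}", f"cost_{slug}"]
        for name in required:
            if name not in self.specs:
                raise ParameterError(f"missing required parameter {name!r}")
        for name, dflt in STRUCTURAL_DEFAULTS.items():
            if name not in self.specs:
                self.specs[name] = ParameterSpec(name, dflt[1], dflt[0], dflt[2])
        for name, spec in self.specs.items():
            if name != spec.name:
                raise ParameterError(f"key {name!r} does not match spec name {spec.name!r}")


# ---------------------------------------------------------------------------
# Built-in base case
# ---------------------------------------------------------------------------

_BASECASE_STRATEGIES = (("CE-CT", "cect"), ("MRI", "mri"), ("PET/CT", "petct"))

# (name, value, family); dispersion filled by the 20%-of-mean default rule.
_BASECASE_VALUES = (
    # diagnostic test performance (two-reader averages)
    ("sens_cect", 0.6570, "beta"),
    ("spec_cect", 0.9365, "beta"),
    ("sens_mri", 0.8485, "beta"),
    ("spec_mri", 0.9205, "beta"),
    ("sens_petct", 0.7205, "beta"),
    ("spec_petct", 0.9285, "beta"),
    # acute costs (USD, Medicare tariffs)
    ("cost_cect", 464.00, "gamma"),
    ("cost_mri", 964.00, "gamma"),
    ("cost_petct", 1_615.00, "gamma"),
    ("hospital_day_cost", 2_606.00, "gamma"),
    ("hepatic_resection_cost", 4_450.00, "gamma"),
    ("days_in_hospital", 7.0, "point"),
    ("overall_resection_cost", 21_592.00, "gamma"),
    # delayed treatment after a false negative: 1.3 x timely resection
    ("delayed_resection_cost", 28_069.60, "gamma"),
    # long-term costs
    ("annual_crlm_cost", 63_063.00, "gamma"),
    # utilities
    ("u_tumor_free", 1.0, "beta"),
    ("u_post_resection", 0.78, "beta"),
    ("u_recurrence", 0.65, "beta"),
    ("u_undetected", 0.85, "beta"),
    # transition probabilities
    ("p_treatment_success", 0.70, "beta"),
    ("p_recurrence_5y", 0.62, "beta"),
    ("p_metastases", 0.2750, "beta"),
    ("p_death_untreated", 0.2417, "beta"),
)


def builtin_basecase() -> tuple[ParameterTable, list[StrategySpec]]:
    """The built-in base-case input set and its three imaging strategies.

    Probabilities and utilities carry beta distributions, costs gamma; the
    discount rate (3%/yr), WTP ($100,000/QALY), starting age (68) and the
    cycle structure (annual cycles, default 5) are fixed.  Published sources
    report no standard errors, so every sampled parameter defaults to a
    dispersion of 20% of its mean (capped to keep beta moments feasible).
    """
    specs: dict[str, ParameterSpec] = {}
    for name, value, family in _BASECASE_VALUES:
        specs[name] = ParameterSpec(name, value, family, default_dispersion(value, family))
    table = ParameterTable(
        specs,
        _BASECASE_STRATEGIES,
        discount_rate=0.03,
        wtp=100_000.0,
        horizon=5,
        cycle_length=1.0,
        start_age=68.0,
    )
    return table, table.strategy_specs()


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _read_structured(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParameterError(f"{path}: expected a mapping at top level")
    return data


def _parse_param_entry(name: str, entry) -> ParameterSpec:
    if isinstance(entry, Mapping):
        if "value" not in entry:
            raise ParameterError(f"parameter {name!r}: missing 'value'")
        value = float(entry["value"])
        family = entry.get("dist", "point")
        dispersion = entry.get("dispersion")
        if dispersion is None:
            dispersion = default_dispersion(value, family)
        return ParameterSpec(name, value, family, float(dispersion))
    return ParameterSpec(name, float(entry))


def load_parameter_table(path: str | Path) -> ParameterTable:
    """Read a full parameter table from a YAML/JSON config file.

    The file has three sections: ``settings`` (discount_rate, wtp, horizon,
    cycle_length, start_age, optional recurrence_input), ``strategies``
    (list of ``{label, slug}``) and ``parameters`` (name -> either a bare
    value or ``{value, dist, dispersion}``).  ``write_parameter_table``
    followed by this function is the identity.
    """
    data = _read_structured(path)
    settings = data.get("settings")
    if settings is None:
        raise ParameterError(f"{path}: missing 'settings' section")
    for key in REQUIRED_SETTINGS:
        if key not in settings:
            raise ParameterError(f"{path}: missing setting {key!r}")
    raw_strategies = data.get("strategies")
    if not raw_strategies:
        raise ParameterError(f"{path}: missing 'strategies' section")
    strategies = tuple((s["label"], s["slug"]) for s in raw_strategies)
    raw_params = data.get("parameters")
    if not raw_params:
        raise ParameterError(f"{path}: missing 'parameters' section")
    specs = {name: _parse_param_entry(name, entry) for name, entry in raw_params.items()}
    return ParameterTable(
        specs,
        strategies,
        discount_rate=float(settings["discount_rate"]),
        wtp=float(settings["wtp"]),
        horizon=int(settings["horizon"]),
        cycle_length=float(settings["cycle_length"]),
        start_age=float(settings["start_age"]),
        recurrence_input=settings.get("recurrence_input", "cumulative_5y"),
    )


def write_parameter_table(table: ParameterTable, path: str | Path) -> None:
    """Serialise a table to YAML (or JSON if the suffix is .json)."""
    data = {
        "settings": {
            "discount_rate": table.discount_rate,
            "wtp": table.wtp,
            "horizon": table.horizon,
            "cycle_length": table.cycle_length,
            "start_age": table.start_age,
            "recurrence_input": table.recurrence_input,
        },
        "strategies": [{"label": lab, "slug": slug} for lab, slug in table.strategies],
        "parameters": {
            s.name: {"value": s.base_value, "dist": s.dist_family, "dispersion": s.dispersion}
            for s in table.specs.values()
        },
    }
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_overrides(path: str | Path) -> dict:
    """Read a partial config (the same dialect, any subset of keys)."""
    return _read_structured(path)


def apply_overrides(table: ParameterTable, overrides: Mapping) -> ParameterTable:
    """Apply a partial config on top of an existing table."""
    for key, val in (overrides.get("settings") or {}).items():
        table = table.with_settings(**{key: val})
    for name, entry in (overrides.get("parameters") or {}).items():
        if isinstance(entry, Mapping):
            old = table.specs.get(name)
            value = float(entry.get("value", old.base_value if old else 0.0))
            family = entry.get("dist", old.dist_family if old else "point")
            dispersion = entry.get("dispersion")
            if dispersion is None:
                dispersion = old.dispersion if old and old.dist_family == family else (
                    default_dispersion(value, family)
                )
            table = table.with_spec(ParameterSpec(name, value, family, float(dispersion)))
        else:
            table = table.replace_values(**{name: float(entry)})
    return table


def export_csv(table: ParameterTable, path: str | Path) -> None:
    """Flat CSV export: name,value,dist,dispersion."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "value", "dist", "dispersion"])
        for s in table.specs.values():
            writer.writerow([s.name, s.base_value, s.dist_family, s.dispersion])
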