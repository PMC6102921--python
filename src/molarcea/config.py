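"""Declarative model specification: states, strategies, parameters.

A model is described by a YAML document with four sections:

``settings``
    ``start_age`` (years), ``horizon`` (cycles), ``cycle_length`` (years),
    ``discount_rate`` (per year), and optional convention switches
    ``half_cycle_correction`` (default false) and ``use_failure_qol``
    (default false; accrue a distinct utility in the cycle a prosthesis
    fails).
``life_table``
    Either ``kind: gompertz`` with ``anchors: {age: q}`` (interpolated over
    the modelled age range) or ``kind: table`` with an explicit ``q`` map.
``parameters``
    Named distributions, ``{family: beta|gamma|fixed, mean, sd}``, fitted by
    the method of moments.  State fields may refer to these by name.
``states`` / ``strategies``
    One entry per health state (entry cost, per-cycle maintenance cost,
    per-cycle QOL, annual failure rate, failure allocation) and the initial
    state of each treatment strategy.

Scalar state fields may be literal numbers or the name of a parameter; the
point value of a referenced parameter is its mean.  ``resolve()`` turns the
spec into flat numeric arrays for the cohort engine, optionally overriding
parameter values (used by the sensitivity analyses).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import IO, Mapping

import numpy as np
import yaml

from .distributions import (
    DistributionSpec,
    fit_beta_from_moments,
    fit_gamma_from_moments,
    fixed_value,
)
from .lifetable import LifeTable, build_life_table

__all__ = [
    "ConfigError",
    "HealthState",
    "ModelSpec",
    "ResolvedModel",
    "convert_gohai",
    "load_model_spec",
    "load_reference_model",
    "GOHAI_MIN",
    "GOHAI_MAX",
]

GOHAI_MIN = 12
GOHAI_MAX = 60

DEAD = "dead"

REFERENCE_MODEL = "molar_model.yaml"


class ConfigError(ValueError):
    pass


def convert_gohai(raw_score):
    """Rescale a raw GOHAI total (12-60) linearly onto [0, 1].

    0 is no satisfaction (maximal oral limitation), 1 full satisfaction.
    Accepts scalars or arrays; raises :class:`ConfigError` out of range.
    """
    arr = np.asarray(raw_score, dtype=float)
    if np.any(arr < GOHAI_MIN) or np.any(arr > GOHAI_MAX):
        raise ConfigError(
            f"GOHAI score outside [{GOHAI_MIN}, {GOHAI_MAX}]: {raw_score}"
        )
    out = (arr - GOHAI_MIN) / (GOHAI_MAX - GOHAI_MIN)
    return float(out) if np.isscalar(raw_score) or arr.ndim == 0 else out


@dataclass(frozen=True)
class HealthState:
    """One Markov state.  Scalar fields are numbers or parameter names."""

    name: str
    entry_cost: float | str = 0.0
    maintenance_cost: float | str = 0.0
    qol: float | str = 0.0
    annual_failure_rate: float | str = 0.0
    failure_allocation: tuple[tuple[str, float], ...] = ()
    failure_qol: float | str | None = None


@dataclass(frozen=True)
class ResolvedModel:
    """Flat numeric view of a model, ready for the cohort engine."""

    state_names: tuple[str, ...]
    entry_cost: np.ndarray  # (S,) EUR charged on entering the state
    maintenance_cost: np.ndarray  # (S,) EUR per cycle occupied
    qol: np.ndarray  # (S,) per-cycle effectiveness in [0, 1]
    failure_rate: np.ndarray  # (S,) annual probability
    allocation: np.ndarray  # (S, S) destination split given failure
    failure_qol: np.ndarray  # (S,) utility in the failure cycle
    dead_index: int

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def index(self, name: str) -> int:
        return self.state_names.index(name)


@dataclass(frozen=True)
class ModelSpec:
    states: dict[str, HealthState]
    strategies: dict[str, str]  # strategy name -> initial state
    start_age: int
    horizon: int
    cycle_length: float
    discount_rate: float
    life_table: LifeTable
    parameters: dict[str, DistributionSpec] = field(default_factory=dict)
    half_cycle_correction: bool = False
    use_failure_qol: bool = False

    # -- parameter plumbing ----------------------------------------------
    def parameter_values(self) -> dict[str, float]:
        """Point (mean) value of every named parameter."""
        return {name: d.mean for name, d in self.parameters.items()}

    def _scalar(self, value, overrides: Mapping[str, float] | None) -> float:
        if isinstance(value, str):
            if overrides and value in overrides:
                return float(overrides[value])
            return self.parameters[value].mean
        return float(value)

    def resolve(
        self, overrides: Mapping[str, float] | None = None
    ) -> ResolvedModel:
        """Materialise numeric arrays, optionally overriding parameters."""
        if overrides:
            unknown = set(overrides) - set(self.parameters)
            if unknown:
                raise ConfigError(f"unknown parameter override(s): {unknown}")
        names = tuple(self.states)
        idx = {n: i for i, n in enumerate(names)}
        S = len(names)
        entry = np.zeros(S)
        maint = np.zeros(S)
        qol = np.zeros(S)
        fail = np.zeros(S)
        fqol = np.zeros(S)
        alloc = np.zeros((S, S))
        for i, n in enumerate(names):
            st = self.states[n]
            entry[i] = self._scalar(st.entry_cost, overrides)
            maint[i] = self._scalar(st.maintenance_cost, overrides)
            qol[i] = self._scalar(st.qol, overrides)
            fail[i] = self._scalar(st.annual_failure_rate, overrides)
            fqol[i] = (
                qol[i]
                if st.failure_qol is None
                else self._scalar(st.failure_qol, overrides)
            )
            for dest, p in st.failure_allocation:
                alloc[i, idx[dest]] = p
        return ResolvedModel(
            names, entry, maint, qol, fail, alloc, fqol, idx[DEAD]
        )

    def samples_failure_rates(self) -> bool:
        """True when any failure rate is bound to a sampled parameter."""
        return any(
            isinstance(st.annual_failure_rate, str)
            and self.parameters[st.annual_failure_rate].family != "fixed"
            for st in self.states.values()
        )

    def with_settings(self, **kwargs) -> "ModelSpec":
        return replace(self, **kwargs)

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        def f(v):
            return v if isinstance(v, str) else float(v)

        states = {}
        for n, st in self.states.items():
            d: dict = {
                "entry_cost": f(st.entry_cost),
                "maintenance_cost": f(st.maintenance_cost),
                "qol": f(st.qol),
                "annual_failure_rate": f(st.annual_failure_rate),
                "failure_allocation": {
                    dest: float(p) for dest, p in st.failure_allocation
                },
            }
            if st.failure_qol is not None:
                d["failure_qol"] = f(st.failure_qol)
            states[n] = d
        return {
            "settings": {
                "start_age": self.start_age,
                "horizon": self.horizon,
                "cycle_length": self.cycle_length,
                "discount_rate": self.discount_rate,
                "half_cycle_correction": self.half_cycle_correction,
                "use_failure_qol": self.use_failure_qol,
            },
            "life_table": {"kind": "table", "q": self.life_table.to_dict()},
            "parameters": {
                n: d.to_dict() for n, d in self.parameters.items()
            },
            "states": states,
            "strategies": dict(self.strategies),
        }


# ---------------------------------------------------------------------------
# loading / validation


def _require(doc: Mapping, key: str, where: str):
    if not isinstance(doc, Mapping) or key not in doc:
        raise ConfigError(f"missing required section/field {key!r} in {where}")
    return doc[key]


def _parse_distribution(name: str, d: Mapping) -> DistributionSpec:
    family = _require(d, "family", f"parameter {name!r}")
    mean = float(_require(d, "mean", f"parameter {name!r}"))
    if family == "fixed":
        return fixed_value(mean)
    sd = float(_require(d, "sd", f"parameter {name!r}"))
    try:
        if family == "beta":
            return fit_beta_from_moments(mean, sd)
        if family == "gamma":
            return fit_gamma_from_moments(mean, sd)
    except ValueError as e:
        raise ConfigError(f"parameter {name!r}: {e}") from e
    raise ConfigError(f"parameter {name!r}: unknown family {family!r}")


def _parse_life_table(doc: Mapping, start_age: int, horizon: int) -> LifeTable:
    kind = doc.get("kind", "gompertz")
    age_range = (start_age, start_age + horizon)
    try:
        if kind == "gompertz":
            anchors = {
                int(a): float(q)
                for a, q in _require(doc, "anchors", "life_table").items()
            }
            return build_life_table(anchors, age_range)
        if kind == "table":
            table = LifeTable(
                {int(a): float(q) for a, q in _require(doc, "q", "life_table").items()}
            )
            if not table.covers(*age_range):
                raise ConfigError(
                    f"life table must cover ages {age_range[0]}-{age_range[1]}"
                )
            return table
    except ConfigError:
        raise
    except ValueError as e:
        raise ConfigError(f"life_table: {e}") from e
    raise ConfigError(f"life_table: unknown kind {kind!r}")


def load_model_spec(source: str | IO | Mapping) -> ModelSpec:
    """Load and validate a model spec from a YAML path, stream or mapping."""
    if isinstance(source, Mapping):
        doc = source
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or not doc:
        raise ConfigError("empty or malformed model document")

    settings = _require(doc, "settings", "document")
    start_age = int(_require(settings, "start_age", "settings"))
    horizon = int(_require(settings, "horizon", "settings"))
    cycle_length = float(settings.get("cycle_length", 1.0))
    discount_rate = float(_require(settings, "discount_rate", "settings"))
    if horizon < 1:
        raise ConfigError("settings.horizon must be >= 1")
    if discount_rate < 0:
        raise ConfigError("settings.discount_rate must be >= 0")

    parameters = {
        str(n): _parse_distribution(str(n), d)
        for n, d in (doc.get("parameters") or {}).items()
    }

    states_doc = _require(doc, "states", "document")
    if DEAD not in states_doc:
        raise ConfigError(f"states must include the absorbing state {DEAD!r}")

    def scalar_field(state: str, fieldname: str, value, allow_ref=True):
        if isinstance(value, str):
            if not allow_ref:
                raise ConfigError(
                    f"state {state!r}: field {fieldname!r} cannot be a reference"
                )
            if value not in parameters:
                raise ConfigError(
                    f"state {state!r}: field {fieldname!r} references "
                    f"unknown parameter {value!r}"
                )
            return value
        return float(value)

    states: dict[str, HealthState] = {}
    for name, sd in states_doc.items():
        name = str(name)
        sd = sd or {}
        alloc_doc = sd.get("failure_allocation") or {}
        alloc = tuple((str(d), float(p)) for d, p in alloc_doc.items())
        st = HealthState(
            name=name,
            entry_cost=scalar_field(name, "entry_cost", sd.get("entry_cost", 0.0)),
            maintenance_cost=scalar_field(
                name, "maintenance_cost", sd.get("maintenance_cost", 0.0)
            ),
            qol=scalar_field(name, "qol", sd.get("qol", 0.0)),
            annual_failure_rate=scalar_field(
                name, "annual_failure_rate", sd.get("annual_failure_rate", 0.0)
            ),
            failure_allocation=alloc,
            failure_qol=(
                scalar_field(name, "failure_qol", sd["failure_qol"])
                if "failure_qol" in sd
                else None
            ),
        )
        states[name] = st

    # structural validation
    for name, st in states.items():
        for dest, p in st.failure_allocation:
            if dest not in states:
                raise ConfigError(
                    f"state {name!r}: allocation destination {dest!r} "
                    "is not a declared state"
                )
            if not 0.0 <= p <= 1.0:
                raise ConfigError(
                    f"state {name!r}: allocation probability {p} outside [0, 1]"
                )
        rate = st.annual_failure_rate
        rate_val = parameters[rate].mean if isinstance(rate, str) else rate
        if not 0.0 <= rate_val <= 1.0:
            raise ConfigError(
                f"state {name!r}: annual failure rate {rate_val} outside [0, 1]"
            )
        if rate_val > 0:
            total = sum(p for _, p in st.failure_allocation)
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"state {name!r}: failure allocation sums to {total}, not 1"
                )
    dead = states[DEAD]
    if dead.failure_allocation or (
        isinstance(dead.annual_failure_rate, float)
        and dead.annual_failure_rate != 0.0
    ):
        raise ConfigError("dead state must have no exits")

    strategies_doc = _require(doc, "strategies", "document")
    strategies = {}
    for sname, initial in strategies_doc.items():
        if initial not in states:
            raise ConfigError(
                f"strategy {sname!r}: initial state {initial!r} not declared"
            )
        strategies[str(sname)] = str(initial)
    if not strategies:
        raise ConfigError("at least one strategy is required")

    life_table = _parse_life_table(
        _require(doc, "life_table", "document"), start_age, horizon
    )

    return ModelSpec(
        states=states,
        strategies=strategies,
        start_age=start_age,
        horizon=horizon,
        cycle_length=cycle_length,
        discount_rate=discount_rate,
        life_table=life_table,
        parameters=parameters,
        half_cycle_correction=bool(settings.get("half_cycle_correction", False)),
        use_failure_qol=bool(settings.get("use_failure_qol", False)),
    )


def load_reference_model() -> ModelSpec:
    """The packaged single-molar prosthesis model (Japanese payer setting)."""
    ref = importlib.resources.files("molarcea.data") / REFERENCE_MODEL
    with ref.open() as fh:
        return load_model_spec(fh)
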