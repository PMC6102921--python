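"""Discrete-time Markov cohort engine.

The cohort starts with proportion 1 in a strategy's initial state and is
propagated over annual cycles.  Within a cycle, death (age-dependent, from
the life table) competes first; the annual failure rate then applies to
survivors and the failing flow is split over the allocation destinations:

    P(s -> dead) = q(age)
    P(s -> d)    = (1 - q(age)) * f_s * a_{s,d}
    P(s -> s)   += (1 - q(age)) * (1 - f_s)

Accrual conventions (defaults; switches live on the model settings):

* effects and maintenance costs accrue on start-of-cycle occupancy, cycle 0
  undiscounted, discount factor (1 + r)^(-t);
* the full treatment (entry) cost of a destination state is charged to the
  flow entering it at the transition, discounted at the arrival cycle, plus
  the initial state's entry cost at t = 0;
* optional half-cycle correction instead weights the boundary cycles
  (0 and ``horizon``) by one half;
* optional failure-cycle utility: the flow failing out of a state accrues
  that state's ``failure_qol`` ("lost prosthesis" utility) for that cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .config import ModelSpec, ResolvedModel

__all__ = [
    "discount_factor",
    "transition_matrix",
    "run_cohort",
    "base_case",
    "CohortTrace",
    "StrategyResult",
]


def discount_factor(rate: float, cycle: int):
    """Present-value multiplier (1 + rate)^(-cycle) for a cycle index.

    ``cycle`` may be an integer or an integer array; it must be >= 0.
    """
    cyc = np.asarray(cycle)
    if np.any(cyc < 0):
        raise ValueError(f"cycle must be non-negative, got {cycle}")
    if rate < 0:
        raise ValueError(f"discount rate must be non-negative, got {rate}")
    out = (1.0 + rate) ** (-cyc.astype(float))
    return float(out) if np.isscalar(cycle) else out


def _as_resolved(
    model: ModelSpec | ResolvedModel,
    overrides: Mapping[str, float] | None = None,
) -> ResolvedModel:
    if isinstance(model, ResolvedModel):
        if overrides:
            raise ValueError("overrides require an unresolved ModelSpec")
        return model
    return model.resolve(overrides)


def transition_matrix(
    model: ModelSpec | ResolvedModel,
    age: int,
    *,
    life_table=None,
    overrides: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Row-stochastic one-cycle transition matrix at a given age."""
    if life_table is None:
        if not isinstance(model, ModelSpec):
            raise ValueError("life_table required with a ResolvedModel")
        life_table = model.life_table
    rm = _as_resolved(model, overrides)
    q = life_table(age)  # raises outside the covered range
    S = rm.n_states
    M = np.zeros((S, S))
    surv = 1.0 - q
    for i in range(S):
        if i == rm.dead_index:
            M[i, i] = 1.0
            continue
        f = rm.failure_rate[i]
        M[i, rm.dead_index] = q
        M[i] += surv * f * rm.allocation[i]
        M[i, i] += surv * (1.0 - f)
    return M


@dataclass(frozen=True)
class StrategyResult:
    """Total discounted cost (EUR) and effectiveness (GOHAI-scaled years)."""

    strategy: str
    cost: float
    effectiveness: float


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle cohort distribution and discounted accruals for a strategy.

    ``occupancy`` has ``horizon + 1`` rows (cycle 0 .. horizon); accrual
    arrays have the same length, with the final row carrying only the entry
    cost of transitions completing at the horizon boundary.
    """

    strategy: str
    state_names: tuple[str, ...]
    start_age: int
    occupancy: np.ndarray  # (horizon+1, S)
    disc_cost: np.ndarray  # (horizon+1,) EUR
    disc_effect: np.ndarray  # (horizon+1,) GOHAI-scaled years
    disc_state_years: np.ndarray  # (S,) discounted occupancy-years (accrued cycles)
    disc_entry_flow: np.ndarray  # (S,) discounted entering flow incl. t=0 start

    @property
    def total_cost(self) -> float:
        return float(self.disc_cost.sum())

    @property
    def total_effect(self) -> float:
        return float(self.disc_effect.sum())

    @property
    def result(self) -> StrategyResult:
        return StrategyResult(self.strategy, self.total_cost, self.total_effect)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cycle/per-state trace (occupancy shares)."""
        horizon = self.occupancy.shape[0] - 1
        cycles = np.arange(horizon + 1)
        rows = []
        for t in cycles:
            for j, s in enumerate(self.state_names):
                rows.append(
                    (
                        int(t),
                        self.start_age + int(t),
                        s,
                        self.occupancy[t, j],
                        self.disc_cost[t],
                        self.disc_effect[t],
                    )
                )
        return pd.DataFrame(
            rows,
            columns=["cycle", "age", "state", "occupancy", "disc_cost", "disc_effect"],
        )


def run_cohort(
    spec: ModelSpec,
    strategy: str,
    *,
    overrides: Mapping[str, float] | None = None,
) -> CohortTrace:
    """Run the cohort for one strategy and return its trace.

    ``strategy`` may be a declared strategy name or a state name.
    ``overrides`` substitutes parameter values (point sensitivity / PSA).
    """
    initial = spec.strategies.get(strategy, strategy)
    if initial not in spec.states:
        raise ValueError(
            f"unknown strategy or state {strategy!r}; "
            f"declared strategies: {sorted(spec.strategies)}"
        )
    rm = spec.resolve(overrides)
    S = rm.n_states
    horizon = spec.horizon
    r = spec.discount_rate
    i0 = rm.index(initial)

    occ = np.zeros((horizon + 1, S))
    occ[0, i0] = 1.0
    disc_cost = np.zeros(horizon + 1)
    disc_effect = np.zeros(horizon + 1)
    state_years = np.zeros(S)
    entry_flow = np.zeros(S)

    v = discount_factor(r, np.arange(horizon + 1))
    weights = np.ones(horizon + 1)
    weights[-1] = 0.0  # no occupancy accrual beyond the horizon
    if spec.half_cycle_correction:
        weights = np.ones(horizon + 1)
        weights[0] = weights[-1] = 0.5

    entry_flow[i0] = 1.0
    disc_cost[0] += rm.entry_cost[i0]  # initial treatment, undiscounted

    for t in range(horizon):
        q = spec.life_table(spec.start_age + t)
        surv = 1.0 - q
        row = occ[t]

        # occupancy-based accrual for cycle t
        w = weights[t] * v[t]
        eff_t = row @ rm.qol
        if spec.use_failure_qol:
            fail_flow = row * surv * rm.failure_rate
            eff_t += fail_flow @ (rm.failure_qol - rm.qol)
        disc_effect[t] += w * eff_t
        disc_cost[t] += w * (row @ rm.maintenance_cost)
        state_years += w * row

        # transition into cycle t+1
        M = transition_matrix(rm, spec.start_age + t, life_table=spec.life_table)
        flow = row[:, None] * M
        new = flow.sum(axis=0)
        inflow = new - np.diag(flow)  # entries, excluding stayers
        disc_cost[t + 1] += v[t + 1] * (inflow @ rm.entry_cost)
        entry_flow += v[t + 1] * inflow
        occ[t + 1] = new

    if spec.half_cycle_correction:
        t = horizon
        w = weights[t] * v[t]
        disc_effect[t] += w * (occ[t] @ rm.qol)
        disc_cost[t] += w * (occ[t] @ rm.maintenance_cost)
        state_years += w * occ[t]

    return CohortTrace(
        strategy=strategy,
        state_names=rm.state_names,
        start_age=spec.start_age,
        occupancy=occ,
        disc_cost=disc_cost,
        disc_effect=disc_effect,
        disc_state_years=state_years,
        disc_entry_flow=entry_flow,
    )


def base_case(
    spec: ModelSpec, overrides: Mapping[str, float] | None = None
) -> dict[str, CohortTrace]:
    """Run every declared strategy at the point parameter values."""
    return {
        name: run_cohort(spec, name, overrides=overrides)
        for name in spec.strategies
    }
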