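"""Probabilistic sensitivity analysis and acceptability curves.

Each Monte-Carlo iteration draws every sampled parameter independently from
its fitted distribution (beta for QOL, gamma for cost), reruns the cohort
model for every strategy and records total discounted cost and
effectiveness.  Acceptability at a willingness-to-pay threshold is the
fraction of iterations in which a strategy attains the maximum net monetary
benefit, with exact ties split equally.

When no sampled parameter enters the transition structure (the default:
failure rates and allocations are fixed), the state-occupancy trace is
identical across draws, so per-draw totals are the same linear functionals
of the sampled cost/QOL vectors that a full rerun would produce; they are
then evaluated in closed form from a single trace per strategy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelSpec
from .engine import run_cohort

__all__ = ["PsaResult", "Ceac", "run_psa", "compute_ceac", "default_wtp_grid"]


def default_wtp_grid(wtp_max: float = 5000.0, wtp_step: float = 100.0):
    """Willingness-to-pay grid 0..wtp_max (EUR per effectiveness unit)."""
    return np.arange(0.0, wtp_max + wtp_step / 2, wtp_step)


@dataclass(frozen=True)
class PsaResult:
    """Per-iteration strategy totals from a seeded Monte-Carlo run."""

    strategies: tuple[str, ...]
    costs: np.ndarray  # (n_iter, K) EUR
    effects: np.ndarray  # (n_iter, K) GOHAI-scaled years
    draws: pd.DataFrame  # (n_iter, P) sampled parameter values
    seed: int
    n_iter: int

    def mean_results(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strategy": self.strategies,
                "mean_cost": self.costs.mean(axis=0),
                "mean_effectiveness": self.effects.mean(axis=0),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy cost-effectiveness-plane scatter (one row per draw/strategy)."""
        n, k = self.costs.shape
        return pd.DataFrame(
            {
                "iteration": np.repeat(np.arange(n), k),
                "strategy": np.tile(self.strategies, n),
                "cost": self.costs.ravel(),
                "effectiveness": self.effects.ravel(),
            }
        )


@dataclass(frozen=True)
class Ceac:
    """Probability each strategy is optimal on a willingness-to-pay grid."""

    wtp: np.ndarray  # (W,) EUR per effectiveness unit
    strategies: tuple[str, ...]
    probability: np.ndarray  # (W, K), rows sum to 1

    def to_frame(self) -> pd.DataFrame:
        w = len(self.wtp)
        k = len(self.strategies)
        return pd.DataFrame(
            {
                "wtp": np.repeat(self.wtp, k),
                "strategy": np.tile(self.strategies, w),
                "probability": self.probability.ravel(),
            }
        )


def _sample_parameters(
    spec: ModelSpec, n_iter: int, rng: np.random.Generator
) -> pd.DataFrame:
    cols = {}
    for name, dist in spec.parameters.items():
        cols[name] = np.asarray(dist.sample(rng, n_iter), dtype=float)
    return pd.DataFrame(cols)


def run_psa(spec: ModelSpec, n_iter: int, seed: int) -> PsaResult:
    """Seeded Monte-Carlo propagation of parameter uncertainty."""
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    for name, dist in spec.parameters.items():
        if dist.family not in ("beta", "gamma", "fixed"):
            raise ValueError(f"parameter {name!r}: unsupported distribution")
    rng = np.random.default_rng(seed)
    draws = _sample_parameters(spec, n_iter, rng)
    strategies = tuple(spec.strategies)
    K = len(strategies)

    fast = not spec.samples_failure_rates() and not spec.use_failure_qol
    costs = np.empty((n_iter, K))
    effects = np.empty((n_iter, K))

    if fast:
        # one trace per strategy; totals are linear in the sampled vectors
        pnames = list(spec.parameters)
        pindex = {n: j for j, n in enumerate(pnames)}
        D = draws.to_numpy()  # (n, P)

        def field_matrix(getter):
            """(n_iter, S) values of a state field under each draw."""
            cols = []
            for st in spec.states.values():
                v = getter(st)
                if isinstance(v, str):
                    cols.append(D[:, pindex[v]])
                else:
                    cols.append(np.full(n_iter, float(v)))
            return np.column_stack(cols)

        entry = field_matrix(lambda st: st.entry_cost)
        maint = field_matrix(lambda st: st.maintenance_cost)
        qol = field_matrix(lambda st: st.qol)
        for k, name in enumerate(strategies):
            trace = run_cohort(spec, name)
            u = trace.disc_state_years  # (S,)
            w = trace.disc_entry_flow  # (S,)
            costs[:, k] = entry @ w + maint @ u
            effects[:, k] = qol @ u
    else:
        for i in range(n_iter):
            overrides = {n: draws.iloc[i][n] for n in draws.columns}
            for k, name in enumerate(strategies):
                res = run_cohort(spec, name, overrides=overrides).result
                costs[i, k] = res.cost
                effects[i, k] = res.effectiveness

    return PsaResult(
        strategies=strategies,
        costs=costs,
        effects=effects,
        draws=draws,
        seed=int(seed),
        n_iter=int(n_iter),
    )


def compute_ceac(psa: PsaResult, wtp_grid=None) -> Ceac:
    """Acceptability: P(max net monetary benefit) per strategy and WTP."""
    if psa.n_iter < 1 or psa.costs.size == 0:
        raise ValueError("empty PSA result")
    wtp = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, float)
    if wtp.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    if np.any(wtp < 0):
        raise ValueError("willingness-to-pay values must be non-negative")
    probs = np.empty((wtp.size, len(psa.strategies)))
    for i, lam in enumerate(wtp):
        nmb = lam * psa.effects - psa.costs  # (n, K)
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb == best  # exact ties share the win
        probs[i] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    return Ceac(wtp=wtp, strategies=psa.strategies, probability=probs)
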