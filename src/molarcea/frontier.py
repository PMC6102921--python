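"""Incremental cost-effectiveness analysis: dominance and the frontier.

Strategies are ordered by effectiveness.  A strategy is *dominated* when
another costs no more and is at least as effective (one strictly); it is
*extended dominated* when its incremental cost-effectiveness ratio against
the previous frontier point exceeds that of the next frontier point against
itself, so that a mixture of its neighbours would outperform it.  Pairwise
ICERs along the surviving frontier are strictly increasing by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .engine import StrategyResult

__all__ = [
    "UNDOMINATED",
    "DOMINATED",
    "EXTENDED_DOMINATED",
    "FrontierReport",
    "build_frontier",
    "net_monetary_benefit",
]

UNDOMINATED = "undominated"
DOMINATED = "dominated"
EXTENDED_DOMINATED = "extended_dominated"


def net_monetary_benefit(result: StrategyResult, wtp: float) -> float:
    """NMB = wtp * effectiveness - cost, in EUR."""
    if wtp < 0:
        raise ValueError(f"willingness to pay must be non-negative, got {wtp}")
    return wtp * result.effectiveness - result.cost


@dataclass(frozen=True)
class FrontierReport:
    """Dominance classification and pairwise ICERs along the frontier."""

    results: tuple[StrategyResult, ...]  # ordered by effectiveness
    classification: dict[str, str]
    frontier: tuple[str, ...]  # undominated, effectiveness ascending
    increments: tuple[dict, ...]  # per consecutive frontier pair
    equivalent: tuple[tuple[str, str], ...] = ()

    def icer(self, high: str, low: str) -> float:
        """ICER of ``high`` vs ``low`` among the reported increments."""
        for inc in self.increments:
            if inc["strategy"] == high and inc["versus"] == low:
                return inc["icer"]
        raise KeyError(f"no frontier increment {high!r} vs {low!r}")

    def to_frame(self) -> pd.DataFrame:
        """Incremental analysis table (one row per strategy)."""
        inc_by_strategy = {d["strategy"]: d for d in self.increments}
        rows = []
        for res in self.results:
            inc = inc_by_strategy.get(res.strategy)
            rows.append(
                {
                    "strategy": res.strategy,
                    "cost": res.cost,
                    "incr_cost": inc["incr_cost"] if inc else math.nan,
                    "effectiveness": res.effectiveness,
                    "incr_effectiveness": (
                        inc["incr_effectiveness"] if inc else math.nan
                    ),
                    "icer": inc["icer"] if inc else math.nan,
                    "classification": self.classification[res.strategy],
                }
            )
        return pd.DataFrame(rows)


def _dominates(a: StrategyResult, b: StrategyResult) -> bool:
    """True when a weakly dominates b (one inequality strict)."""
    return (
        a.cost <= b.cost
        and a.effectiveness >= b.effectiveness
        and (a.cost < b.cost or a.effectiveness > b.effectiveness)
    )


def build_frontier(results: Iterable[StrategyResult]) -> FrontierReport:
    """Classify strategies and report ICERs along the efficiency frontier."""
    res = sorted(results, key=lambda r: (r.effectiveness, r.cost, r.strategy))
    if not res:
        raise ValueError("at least one strategy result is required")
    names = [r.strategy for r in res]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy names")
    for r in res:
        if not (math.isfinite(r.cost) and math.isfinite(r.effectiveness)):
            raise ValueError(f"non-finite totals for strategy {r.strategy!r}")

    classification: dict[str, str] = {}
    equivalent: list[tuple[str, str]] = []
    for r in res:
        twins = [
            o.strategy
            for o in res
            if o.strategy != r.strategy
            and o.cost == r.cost
            and o.effectiveness == r.effectiveness
        ]
        for t in twins:
            pair = tuple(sorted((r.strategy, t)))
            if pair not in equivalent:
                equivalent.append(pair)
        if any(
            _dominates(o, r)
            for o in res
            if o.strategy != r.strategy and o.strategy not in twins
        ):
            classification[r.strategy] = DOMINATED

    # candidates sorted by effectiveness; exact (cost, effectiveness) twins
    # are classified with their representative but traversed only once
    candidates = []
    twin_of: dict[str, str] = {}
    seen: dict[tuple[float, float], str] = {}
    for r in res:
        if r.strategy in classification:
            continue
        key = (r.cost, r.effectiveness)
        if key in seen:
            twin_of[r.strategy] = seen[key]
        else:
            seen[key] = r.strategy
            candidates.append(r)

    # extended dominance elimination
    changed = True
    while changed and len(candidates) > 2:
        changed = False
        for k in range(1, len(candidates) - 1):
            lo, mid, hi = candidates[k - 1], candidates[k], candidates[k + 1]
            icer_mid = _pair_icer(mid, lo)
            icer_hi = _pair_icer(hi, mid)
            if icer_mid > icer_hi:
                classification[mid.strategy] = EXTENDED_DOMINATED
                del candidates[k]
                changed = True
                break

    for r in candidates:
        classification[r.strategy] = UNDOMINATED
    for twin, rep in twin_of.items():
        classification[twin] = classification[rep]

    increments = []
    for prev, cur in zip(candidates, candidates[1:]):
        d_cost = cur.cost - prev.cost
        d_eff = cur.effectiveness - prev.effectiveness
        increments.append(
            {
                "strategy": cur.strategy,
                "versus": prev.strategy,
                "incr_cost": d_cost,
                "incr_effectiveness": d_eff,
                "icer": _pair_icer(cur, prev),
            }
        )

    return FrontierReport(
        results=tuple(res),
        classification=classification,
        frontier=tuple(r.strategy for r in candidates),
        increments=tuple(increments),
        equivalent=tuple(equivalent),
    )


def _pair_icer(high: StrategyResult, low: StrategyResult) -> float:
    d_eff = high.effectiveness - low.effectiveness
    d_cost = high.cost - low.cost
    if d_eff == 0.0:
        # equal effectiveness: the cheaper strategy survives; an infinite
        # ratio keeps the costlier one out without dividing by zero
        return math.inf if d_cost > 0 else -math.inf
    return d_cost / d_eff
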