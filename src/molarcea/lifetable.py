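"""Annual all-cause mortality over the modelled age range.

Abridged national life tables print annual death probabilities q(a) only at
a few anchor ages.  Adult mortality is very close to log-linear in age
(Gompertz), so the gap is filled by fitting
``q(a) = q(a0) * exp(b * (a - a0))`` through the endpoint anchors, with any
interior anchors reproduced exactly at their own ages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["LifeTable", "build_life_table"]


class LifeTableError(ValueError):
    pass


@dataclass(frozen=True)
class LifeTable:
    """Map from integer age (years) to annual probability of death."""

    q: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ages = sorted(self.q)
        if not ages:
            raise LifeTableError("life table is empty")
        last = 0.0
        for a in ages:
            v = self.q[a]
            if not 0.0 < v < 1.0:
                raise LifeTableError(f"q({a})={v} outside (0, 1)")
            if v < last:
                raise LifeTableError(f"q({a})={v} decreases with age")
            last = v

    @property
    def min_age(self) -> int:
        return min(self.q)

    @property
    def max_age(self) -> int:
        return max(self.q)

    def __call__(self, age: int) -> float:
        try:
            return self.q[int(age)]
        except KeyError:
            raise LifeTableError(
                f"age {age} outside life table range "
                f"[{self.min_age}, {self.max_age}]"
            ) from None

    def covers(self, lo: int, hi: int) -> bool:
        return all(a in self.q for a in range(lo, hi + 1))

    def to_dict(self) -> dict[int, float]:
        return dict(sorted(self.q.items()))


def build_life_table(
    anchors: dict[int, float], age_range: tuple[int, int]
) -> LifeTable:
    """Fill every integer age in ``age_range`` by Gompertz interpolation.

    The log-linear slope ``b = ln(q_hi/q_lo) / (age_hi - age_lo)`` is fitted
    to the endpoint anchors; interior anchors (if any) override the
    interpolated value exactly at their own age.

    Parameters
    ----------
    anchors : mapping of integer age to annual death probability, at least
        two entries, strictly increasing in both age and q.
    age_range : inclusive (low, high) integer age interval to cover.
    """
    if len(anchors) < 2:
        raise LifeTableError("need at least two anchors")
    ages = sorted(anchors)
    lo, hi = age_range
    if lo > hi:
        raise LifeTableError(f"empty age range {age_range}")
    for a in ages:
        if not lo <= a <= hi:
            raise LifeTableError(f"anchor age {a} outside range {age_range}")
        if not 0.0 < anchors[a] < 1.0:
            raise LifeTableError(f"anchor q({a})={anchors[a]} outside (0, 1)")
    qs = [anchors[a] for a in ages]
    if any(q2 <= q1 for q1, q2 in zip(qs, qs[1:])):
        raise LifeTableError("anchor q values must strictly increase with age")

    a0, a1 = ages[0], ages[-1]
    b = math.log(anchors[a1] / anchors[a0]) / (a1 - a0)
    table = {
        a: anchors[a0] * math.exp(b * (a - a0)) for a in range(lo, hi + 1)
    }
    table.update({a: anchors[a] for a in ages})  # exact anchor passthrough
    return LifeTable(table)
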