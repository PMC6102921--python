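"""One-way deterministic sensitivity analysis (tornado diagram data).

Each parameter is set in turn to a low and a high bound (mean -/+ a multiple
of its SD by default, or explicit bounds), all other parameters held at
baseline, and the ICER of a comparator pair is recomputed with two cohort
runs per bound.  Bounds falling outside a parameter's valid domain (QOL
outside [0, 1], negative costs) are clamped with a logged warning.

When a bound moves the incremental effectiveness across zero the ICER
changes sign; the reported swing is the absolute difference of the signed
ICERs and such entries should be read on the net-benefit scale instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .config import ModelSpec
from .engine import run_cohort

__all__ = ["TornadoEntry", "TornadoReport", "one_way_sensitivity"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_low: float
    icer_high: float

    @property
    def swing(self) -> float:
        return abs(self.icer_high - self.icer_low)


@dataclass(frozen=True)
class TornadoReport:
    comparator: tuple[str, str]  # (more effective, reference)
    base_icer: float
    entries: tuple[TornadoEntry, ...]  # sorted by descending swing

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parameter": e.parameter,
                    "low": e.low,
                    "high": e.high,
                    "icer_low": e.icer_low,
                    "icer_high": e.icer_high,
                    "swing": e.swing,
                }
                for e in self.entries
            ]
        )


def _domain(spec: ModelSpec, name: str) -> tuple[float, float]:
    family = spec.parameters[name].family
    if family == "beta":
        return 0.0, 1.0
    return 0.0, float("inf")


def _clamp(spec: ModelSpec, name: str, value: float) -> float:
    lo, hi = _domain(spec, name)
    if value < lo or value > hi:
        clamped = min(max(value, lo), hi)
        logger.warning(
            "parameter %s: bound %.6g outside valid domain [%g, %g], "
            "clamped to %.6g",
            name,
            value,
            lo,
            hi,
            clamped,
        )
        return clamped
    return value


def _icer(spec: ModelSpec, comparator, overrides) -> float:
    high, low = comparator
    rh = run_cohort(spec, high, overrides=overrides).result
    rl = run_cohort(spec, low, overrides=overrides).result
    d_eff = rh.effectiveness - rl.effectiveness
    d_cost = rh.cost - rl.cost
    if d_eff == 0.0:
        return float("inf") if d_cost > 0 else float("-inf")
    return d_cost / d_eff


def one_way_sensitivity(
    spec: ModelSpec,
    parameters: Sequence[str] | None = None,
    *,
    sd_multiple: float = 1.0,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    comparator: tuple[str, str] = ("Implant", "IFDP"),
) -> TornadoReport:
    """Tornado entries for the ICER of ``comparator[0]`` vs ``comparator[1]``.

    Parameters default to every sampled (non-fixed) model parameter with a
    positive SD.  ``bounds`` overrides the mean +/- ``sd_multiple``*SD range
    for selected parameters.
    """
    for s in comparator:
        if s not in spec.strategies and s not in spec.states:
            raise ValueError(f"unknown comparator strategy {s!r}")
    if parameters is None:
        parameters = [
            n
            for n, d in spec.parameters.items()
            if d.family != "fixed" and d.sd > 0
        ]
    unknown = set(parameters) - set(spec.parameters)
    if unknown:
        raise ValueError(f"unknown parameter(s): {sorted(unknown)}")

    base_icer = _icer(spec, comparator, None)
    entries = []
    for name in parameters:
        dist = spec.parameters[name]
        if bounds and name in bounds:
            lo, hi = bounds[name]
        else:
            lo = dist.mean - sd_multiple * dist.sd
            hi = dist.mean + sd_multiple * dist.sd
        lo = _clamp(spec, name, lo)
        hi = _clamp(spec, name, hi)
        entries.append(
            TornadoEntry(
                parameter=name,
                low=lo,
                high=hi,
                icer_low=_icer(spec, comparator, {name: lo}),
                icer_high=_icer(spec, comparator, {name: hi}),
            )
        )
    entries.sort(key=lambda e: e.swing, reverse=True)
    return TornadoReport(
        comparator=tuple(comparator),
        base_icer=base_icer,
        entries=tuple(entries),
    )
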