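"""Synthetic patient-level GOHAI questionnaires.

The oral-health QOL inputs of the cohort model were estimated from a
12-item GOHAI survey (items scored 1-5, raw total 12-60, rescaled to
[0, 1]).  Patient-level responses are not published, so this module
generates a synthetic stand-in: each patient's converted score is drawn
from the beta distribution moment-matched to the group's published
mean +/- SD, snapped to the 49-point raw grid, and decomposed into twelve
item scores that sum exactly to the raw total.  Item-level patterns are a
random composition and carry no behavioural meaning; only the total feeds
the downstream estimates.

``estimate_group_parameters`` is the estimation step that turns such a
survey back into per-group (mean, SD) on the converted scale.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .config import GOHAI_MAX, GOHAI_MIN, convert_gohai
from .distributions import fit_beta_from_moments

__all__ = ["GROUP_TARGETS", "generate_survey", "estimate_group_parameters"]

N_ITEMS = 12
ITEM_MIN, ITEM_MAX = 1, 5

# (converted mean, converted SD, number of patients) per clinical group,
# matching the satisfaction survey behind the model's QOL parameters
GROUP_TARGETS: dict[str, tuple[float, float, int]] = {
    "Implant": (0.88, 0.14, 168),
    "lost Implant": (0.71, 0.23, 32),
    "FDP": (0.83, 0.13, 65),
    "lost FDP": (0.68, 0.17, 66),
    "RPD": (0.71, 0.23, 45),
    "MT": (0.70, 0.18, 184),
}


def _decompose_total(total: int, rng: np.random.Generator) -> list[int]:
    """Random 12-item composition in [1, 5] summing exactly to ``total``."""
    extra = total - N_ITEMS * ITEM_MIN  # points to spread, 0..48
    span = ITEM_MAX - ITEM_MIN
    items = []
    remaining = extra
    for i in range(N_ITEMS):
        cells_left = N_ITEMS - i - 1
        lo = max(0, remaining - span * cells_left)
        hi = min(span, remaining)
        x = int(rng.integers(lo, hi + 1))
        items.append(ITEM_MIN + x)
        remaining -= x
    order = rng.permutation(N_ITEMS)
    return [items[j] for j in order]


def generate_survey(
    group_targets: Mapping[str, tuple[float, float, int]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-patient questionnaires matching group-level moments.

    Returns a frame with ``patient_id``, ``group``, ``item_1`` ..
    ``item_12``, ``raw_total`` (12-60) and ``converted`` (0-1).  Empirical
    converted moments converge to the targets as group size grows, up to
    the small perturbation introduced by snapping to the raw-score grid.
    """
    targets = GROUP_TARGETS if group_targets is None else dict(group_targets)
    rng = np.random.default_rng(seed)
    records = []
    pid = 0
    for group, (mean, sd, n) in targets.items():
        if n < 2:
            raise ValueError(f"group {group!r}: need n >= 2, got {n}")
        beta = fit_beta_from_moments(mean, sd)  # validates feasibility
        scores = beta.sample(rng, n)
        raw = np.clip(
            np.rint(GOHAI_MIN + scores * (GOHAI_MAX - GOHAI_MIN)),
            GOHAI_MIN,
            GOHAI_MAX,
        ).astype(int)
        for total in raw:
            items = _decompose_total(int(total), rng)
            rec = {"patient_id": pid, "group": group}
            rec.update({f"item_{j + 1}": items[j] for j in range(N_ITEMS)})
            rec["raw_total"] = int(total)
            rec["converted"] = convert_gohai(int(total))
            records.append(rec)
            pid += 1
    return pd.DataFrame(records)


def estimate_group_parameters(survey: pd.DataFrame) -> pd.DataFrame:
    """Per-group sample mean and SD of the converted GOHAI score.

    The SD is the n-1 sample standard deviation; for a single-patient group
    the mean is defined and the SD is reported as NaN (undefined).
    """
    if survey.empty:
        raise ValueError("empty survey")
    converted = survey["raw_total"].map(convert_gohai)
    out = (
        survey.assign(converted=converted)
        .groupby("group", sort=False)["converted"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    if (out["n"] == 0).any():
        raise ValueError("empty group in survey")
    return out
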