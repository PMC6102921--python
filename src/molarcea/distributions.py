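"""Parameter uncertainty distributions fitted by the method of moments.

Health-state utilities live on the unit interval and are given beta
distributions; costs are non-negative and are given gamma distributions.
Both are parameterised from a published mean and standard deviation, the
only information the source tables report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistributionSpec",
    "fit_beta_from_moments",
    "fit_gamma_from_moments",
    "fixed_value",
]


class MomentFitError(ValueError):
    """Raised when a (mean, sd) pair is infeasible for the requested family."""


@dataclass(frozen=True)
class DistributionSpec:
    """A sampled model parameter: point value plus its PSA distribution.

    ``family`` is one of ``"beta"``, ``"gamma"`` or ``"fixed"``.  For a beta
    the shape parameters are stored in ``params`` as ``{"alpha", "beta"}``;
    for a gamma as ``{"shape", "scale"}``; a fixed value has no shape
    parameters and always samples its mean.
    """

    family: str
    mean: float
    sd: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "fixed"):
            raise MomentFitError(f"unknown distribution family {self.family!r}")

    # -- analytic moments -------------------------------------------------
    @property
    def analytic_mean(self) -> float:
        if self.family == "beta":
            a, b = self.params["alpha"], self.params["beta"]
            return a / (a + b)
        if self.family == "gamma":
            return self.params["shape"] * self.params["scale"]
        return self.mean

    @property
    def analytic_sd(self) -> float:
        if self.family == "beta":
            a, b = self.params["alpha"], self.params["beta"]
            return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        if self.family == "gamma":
            return math.sqrt(self.params["shape"]) * self.params["scale"]
        return 0.0

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the fitted distribution (the mean itself if fixed)."""
        if self.family == "beta":
            return rng.beta(self.params["alpha"], self.params["beta"], size)
        if self.family == "gamma":
            return rng.gamma(self.params["shape"], self.params["scale"], size)
        if size is None:
            return self.mean
        return np.full(size, self.mean)

    def to_dict(self) -> dict:
        d: dict = {"family": self.family, "mean": self.mean}
        if self.family != "fixed":
            d["sd"] = self.sd
        return d


def fit_beta_from_moments(mean: float, sd: float) -> DistributionSpec:
    """Fit a beta distribution matching a given mean and SD.

    alpha = m * (m(1-m)/sd^2 - 1), beta = (1-m) * (m(1-m)/sd^2 - 1).
    Feasibility requires 0 < mean < 1 and 0 < sd^2 < mean(1-mean).
    """
    if not 0.0 < mean < 1.0:
        raise MomentFitError(
            f"beta mean must satisfy 0 < mean < 1, got mean={mean}"
        )
    var = sd * sd
    bound = mean * (1.0 - mean)
    if not 0.0 < var:
        raise MomentFitError(f"beta sd must be positive, got sd={sd}")
    if var >= bound:
        raise MomentFitError(
            f"beta variance must satisfy sd^2 < mean(1-mean)={bound:.6g}, "
            f"got sd^2={var:.6g}"
        )
    kappa = bound / var - 1.0
    return DistributionSpec(
        "beta", mean, sd, {"alpha": mean * kappa, "beta": (1.0 - mean) * kappa}
    )


def fit_gamma_from_moments(mean: float, sd: float) -> DistributionSpec:
    """Fit a gamma distribution matching a given mean and SD.

    shape = (mean/sd)^2, scale = sd^2/mean; both inputs must be positive.
    """
    if mean <= 0.0:
        raise MomentFitError(f"gamma mean must be positive, got mean={mean}")
    if sd <= 0.0:
        raise MomentFitError(f"gamma sd must be positive, got sd={sd}")
    return DistributionSpec(
        "gamma", mean, sd, {"shape": (mean / sd) ** 2, "scale": sd * sd / mean}
    )


def fixed_value(value: float) -> DistributionSpec:
    """A degenerate (non-sampled) parameter."""
    return DistributionSpec("fixed", float(value), 0.0)
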