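"""Random sampling primitives: lognormal waiting times and Gaussian noise factors.

All waiting times in the simulator are lognormal.  Two parameterizations are
supported:

* ``natural_moments`` — the pair ``(mean_like, spread_like)`` is the desired
  natural-scale mean and standard deviation of the lognormal variate.  This is
  the reading used for every division/death/activation time distribution.
* ``log_space`` — the pair is the (location, scale) of the underlying normal,
  i.e. ``exp(N(location, scale))``.  Used for the division-destiny
  distribution, whose stated parameters only make sense on the log scale.

Multiplicative Gaussian noise (daughter-to-daughter variation, marker
inheritance) is drawn from ``N(mean, sd)`` with the second argument always a
standard deviation; draws used as multiplicative factors are floored at zero
so times and expression levels stay non-negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "DegenerateTruncationError",
    "LognormalSpec",
    "REDRAW_CAP",
    "gaussian_factor",
    "logspace_params_from_moments",
    "sample_lognormal",
    "sample_lognormal_min_redraw",
]

#: Maximum number of consecutive rejection redraws before giving up.
REDRAW_CAP = 10_000


class DegenerateTruncationError(RuntimeError):
    """Raised when truncation-by-redraw keeps rejecting: essentially all of the
    distribution's mass lies below the requested minimum."""


def logspace_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Convert a natural-scale (mean, SD) pair to lognormal (location, scale).

    The returned parameters satisfy ``E[X] = mean`` and ``SD[X] = sd`` for
    ``X = exp(N(location, scale))``:

        scale^2 = ln(1 + sd^2 / mean^2)
        location = ln(mean) - scale^2 / 2

    ``sd = 0`` yields ``scale = 0``, a point mass at ``mean``.
    """
    if mean <= 0:
        raise ValueError(f"lognormal natural-scale mean must be positive, got {mean}")
    if sd < 0:
        raise ValueError(f"lognormal natural-scale SD must be non-negative, got {sd}")
    scale_sq = math.log1p((sd / mean) ** 2)
    scale = math.sqrt(scale_sq)
    location = math.log(mean) - scale_sq / 2.0
    return location, scale


@dataclass(frozen=True)
class LognormalSpec:
    """A lognormal distribution under one of the two parameterizations."""

    mean_like: float
    spread_like: float
    parameterization: Literal["natural_moments", "log_space"] = "natural_moments"

    def __post_init__(self) -> None:
        if self.parameterization not in ("natural_moments", "log_space"):
            raise ValueError(f"unknown parameterization {self.parameterization!r}")
        if self.spread_like < 0:
            raise ValueError("spread_like must be non-negative")
        if self.parameterization == "natural_moments" and self.mean_like <= 0:
            raise ValueError("natural-scale mean must be positive")

    def log_params(self) -> tuple[float, float]:
        """(location, scale) of the underlying normal."""
        if self.parameterization == "natural_moments":
            return logspace_params_from_moments(self.mean_like, self.spread_like)
        return self.mean_like, self.spread_like

    @property
    def mean(self) -> float:
        """Natural-scale mean, exp(location + scale^2/2)."""
        loc, scale = self.log_params()
        return math.exp(loc + scale**2 / 2.0)

    @property
    def median(self) -> float:
        loc, _ = self.log_params()
        return math.exp(loc)


def sample_lognormal(
    spec: LognormalSpec, n: int | None, rng: np.random.Generator
) -> np.ndarray | float:
    """Draw ``n`` i.i.d. variates from ``spec`` (scalar when ``n`` is None)."""
    if n is not None and n < 0:
        raise ValueError("n must be non-negative")
    loc, scale = spec.log_params()
    return rng.lognormal(loc, scale, size=n)


def sample_lognormal_min_redraw(
    spec: LognormalSpec, min_value: float, rng: np.random.Generator
) -> float:
    """One draw from ``spec`` conditioned on ``X >= min_value``, by rejection.

    Redraws until the draw is at least ``min_value``; after :data:`REDRAW_CAP`
    consecutive rejections a :class:`DegenerateTruncationError` is raised.
    """
    loc, scale = spec.log_params()
    for _ in range(REDRAW_CAP):
        x = rng.lognormal(loc, scale)
        if x >= min_value:
            return x
    raise DegenerateTruncationError(
        f"{REDRAW_CAP} consecutive redraws below min_value={min_value} for {spec}"
    )


def sample_lognormal_min_redraw_vec(
    spec: LognormalSpec, min_value: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Vector version of truncation-by-redraw.

    Draw order is pass-based: one block of ``n`` draws, then repeated redraw
    blocks over the still-offending indices in ascending index order, until
    all values are >= ``min_value``.  This pass structure is part of the
    engine's documented draw-order contract.
    """
    loc, scale = spec.log_params()
    out = rng.lognormal(loc, scale, size=n)
    offenders = np.flatnonzero(out < min_value)
    passes = 0
    while offenders.size:
        passes += 1
        if passes > REDRAW_CAP:
            raise DegenerateTruncationError(
                f"{REDRAW_CAP} redraw passes below min_value={min_value} for {spec}"
            )
        out[offenders] = rng.lognormal(loc, scale, size=offenders.size)
        offenders = offenders[out[offenders] < min_value]
    return out


def gaussian_factor(
    mean: float, sd: float, rng: np.random.Generator, n: int | None = None
) -> np.ndarray | float:
    """Draw from N(mean, sd), floored at 0 (factors multiply non-negative
    quantities, so negative draws are clamped)."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    x = rng.normal(mean, sd, size=n)
    return np.maximum(x, 0.0)
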