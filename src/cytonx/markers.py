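"""Surface-marker levels: initialization, division-coupled inheritance, gating.

Marker levels are arbitrary units; expression changes only upon division, and
never feeds back on a cell's division or death kinetics.  Positivity is
boundary-inclusive (level >= threshold).  The conventional subsets are gated
from CD62L/CD27 positivity: Tcm = CD62L+CD27+, Tem = CD62L-CD27+,
Teff = CD62L-CD27-; the CD62L+CD27- quadrant has no conventional name and is
labelled ``other`` (never silently merged into a subset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import MarkerParams, MarkerThresholds
from .distributions import gaussian_factor

__all__ = [
    "MarkerLevels",
    "SUBSET_LABELS",
    "gate_subset",
    "gate_subsets",
    "inherit_markers",
    "init_markers",
    "is_positive",
    "relative_expression",
]

SUBSET_LABELS = ("Tcm", "Tem", "Teff", "other")


@dataclass(frozen=True)
class MarkerLevels:
    """The (CD62L, CD27, KLRG1) expression triple of one cell."""

    cd62l: float
    cd27: float
    klrg1: float

    def __post_init__(self) -> None:
        if self.cd62l < 0 or self.cd27 < 0 or self.klrg1 < 0:
            raise ValueError("marker levels must be non-negative")


def init_markers(rng: np.random.Generator, params: MarkerParams | None = None) -> MarkerLevels:
    """Naive-cell marker levels: independent N(mean, 0.01) draws per marker.

    Draw order: CD62L, CD27, KLRG1."""
    p = params or MarkerParams()
    return MarkerLevels(
        cd62l=float(gaussian_factor(p.init_mean_cd62l, p.init_sd, rng)),
        cd27=float(gaussian_factor(p.init_mean_cd27, p.init_sd, rng)),
        klrg1=float(gaussian_factor(p.init_mean_klrg1, p.init_sd, rng)),
    )


def inherit_markers(
    mother: MarkerLevels,
    rng: np.random.Generator,
    params: MarkerParams | None = None,
) -> tuple[MarkerLevels, MarkerLevels]:
    """Two daughters' levels: mother's level times independent Gaussian factors.

    The six factors (3 markers x 2 daughters) are mutually independent and
    independent of the division/death clocks.  Draw order: CD62L (daughter 1,
    daughter 2), CD27 (1, 2), KLRG1 (1, 2).  Negative products are clamped to
    zero by the factor floor.
    """
    p = params or MarkerParams()
    cd62l = mother.cd62l * gaussian_factor(p.cd62l_factor_mean, p.cd62l_factor_sd, rng, n=2)
    cd27 = mother.cd27 * gaussian_factor(p.cd27_factor_mean, p.cd27_factor_sd, rng, n=2)
    klrg1 = mother.klrg1 * gaussian_factor(p.klrg1_factor_mean, p.klrg1_factor_sd, rng, n=2)
    d1 = MarkerLevels(float(cd62l[0]), float(cd27[0]), float(klrg1[0]))
    d2 = MarkerLevels(float(cd62l[1]), float(cd27[1]), float(klrg1[1]))
    return d1, d2


def is_positive(
    levels: MarkerLevels, thresholds: MarkerThresholds | None = None
) -> tuple[bool, bool, bool]:
    """(CD62L+, CD27+, KLRG1+) flags; the boundary counts as positive."""
    t = thresholds or MarkerThresholds()
    return (levels.cd62l >= t.cd62l, levels.cd27 >= t.cd27, levels.klrg1 >= t.klrg1)


def gate_subset(levels: MarkerLevels, thresholds: MarkerThresholds | None = None) -> str:
    """Gate one cell into Tcm/Tem/Teff/other from CD62L and CD27 positivity."""
    cd62l_pos, cd27_pos, _ = is_positive(levels, thresholds)
    if cd27_pos:
        return "Tcm" if cd62l_pos else "Tem"
    return "other" if cd62l_pos else "Teff"


def gate_subsets(
    cd62l: np.ndarray, cd27: np.ndarray, thresholds: MarkerThresholds | None = None
) -> np.ndarray:
    """Vectorized gating of many cells; returns an array of subset labels."""
    t = thresholds or MarkerThresholds()
    cd62l_pos = np.asarray(cd62l) >= t.cd62l
    cd27_pos = np.asarray(cd27) >= t.cd27
    out = np.where(
        cd27_pos,
        np.where(cd62l_pos, "Tcm", "Tem"),
        np.where(cd62l_pos, "other", "Teff"),
    )
    return out


def relative_expression(
    levels: MarkerLevels, thresholds: MarkerThresholds | None = None
) -> tuple[float, float, float]:
    """Levels divided by their positivity thresholds; >= 1 means positive."""
    t = thresholds or MarkerThresholds()
    return (levels.cd62l / t.cd62l, levels.cd27 / t.cd27, levels.klrg1 / t.klrg1)
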