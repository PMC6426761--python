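"""The branching-process engine: competing division/death clocks with
stochastic inheritance.

Each cell carries a division clock ``t_p`` and a death clock ``t_d`` drawn at
birth; the earlier clock wins (ties go to division).  A dividing mother's two
daughters share a division base ``t_p_i = t_p_{i-1} * L(mu_p, v_p)`` —
redrawn while below ``t_min`` — perturbed per daughter by independent
``N(1, v_e)`` factors, and each daughter independently inherits the death
clock ``t_d_i = t_d_{i-1} * L(mu_d, sigma_d)``.  Marker levels are inherited
multiplicatively and independently of the clocks.

Model variants
--------------
* ``basic`` — all naive cells are activated at t = 0.
* ``heterogeneous_activation`` — an independent lognormal activation delay
  ``L(mu_a, v_a)`` is added to each naive cell's first-division time.  The
  delay postpones only the first division; it is not inherited — daughters'
  division clocks chain from the naive cell's lognormal base.  By default
  the death clock still runs from t = 0 (the delay shields only the
  division clock); set ``death_clock_includes_activation`` to also postpone
  death.
* ``division_destiny`` — additionally, each family draws a continuous
  division destiny ``D_f`` from a log-space lognormal; a cell of generation g
  may divide only while ``g + 1 <= D_f``.  Cells breaching their destiny
  become quiescent: they neither divide nor die for the rest of the run.

Draw-order contract
-------------------
All stochasticity comes from one ``numpy`` generator seeded with the config
seed, consumed generation-major; within a generation the order is:

1. shared division-base factors for all dividing mothers (ascending index),
   then pass-based redraws over still-offending mothers;
2. per-daughter division noise ``N(1, v_e)``, shape (n, 2) row-major;
3. per-daughter death factors ``L(mu_d, sigma_d)``, shape (n, 2);
4–6. CD62L, CD27, KLRG1 inheritance factors, each shape (n, 2).

Generation 0 draws, in order: first-division bases (with redraw passes),
activation delays (non-basic variants), initial death times, then the three
initial marker blocks.  Division destinies are drawn from an auxiliary
generator seeded from (seed, 1) so that the main event stream is identical
across variants at the same seed (this is what makes coupled-seed
destiny-vs-no-destiny comparisons meaningful).

Cells are stored in creation order: families ascending within generation 0,
daughters in mother order thereafter (two consecutive rows per mother).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .config import ModelConfig
from .distributions import (
    LognormalSpec,
    gaussian_factor,
    sample_lognormal,
    sample_lognormal_min_redraw,
    sample_lognormal_min_redraw_vec,
)
from .markers import MarkerLevels, inherit_markers, init_markers

__all__ = [
    "CellRecord",
    "FATES",
    "PopulationExplosionError",
    "Population",
    "draw_division_destiny",
    "draw_initial_times",
    "resolve_fate",
    "simulate",
    "spawn_daughters",
]

logger = logging.getLogger(__name__)

#: Cell fates. ``alive_at_horizon``: neither clock fired before the horizon.
#: ``quiescent``: division destiny breached — frozen, counted as alive.
FATES = ("divided", "died", "alive_at_horizon", "quiescent")
DIVIDED, DIED, ALIVE, QUIESCENT = range(4)
_FATE_ARRAY = np.array(FATES)

#: Persistent fates: cells that are still present at the horizon.
PERSISTENT_FATES = frozenset({"alive_at_horizon", "quiescent"})


class PopulationExplosionError(RuntimeError):
    """Total cell count exceeded the configured hard cap."""

    def __init__(self, generation: int, total: int, cap: int):
        self.generation = generation
        super().__init__(
            f"population exceeded max_cells={cap} at generation {generation} "
            f"({total} cells created)"
        )


@dataclass
class CellRecord:
    """One cell of the lineage tree (scalar counterpart of a table row).

    ``t_p_base`` is the heritable division clock passed on to daughters.  It
    equals ``t_p`` for every divided-from cell except generation-0 cells in
    the activation variants, whose realized first-division time is
    ``t_p = t_p_base + activation delay``; the delay itself is never
    inherited.
    """

    cell_id: int
    family_id: int
    parent_id: int | None
    generation: int
    birth_time: float
    t_p: float
    t_d: float
    markers: MarkerLevels
    fate: str | None = None
    end_time: float | None = None
    t_p_base: float | None = None

    def __post_init__(self) -> None:
        if self.t_p_base is None:
            self.t_p_base = self.t_p


# --------------------------------------------------------------------------
# scalar operations (per-cell API; the vectorized engine below is equivalent)


def _clock_specs(config: ModelConfig) -> dict[str, LognormalSpec]:
    return {
        "mp": LognormalSpec(config.mu_mp, config.v_mp_eff),
        "p": LognormalSpec(config.mu_p, config.v_p_eff),
        "md": LognormalSpec(config.mu_md, config.sigma_md_eff),
        "d": LognormalSpec(config.mu_d, config.sigma_d_eff),
        "a": LognormalSpec(config.mu_a, config.v_a_eff),
        "div": LognormalSpec(config.mu_div, config.v_div, config.destiny_parameterization),
    }


def draw_initial_state(
    config: ModelConfig, rng: np.random.Generator
) -> tuple[float, float, float]:
    """Draw one naive cell's (heritable division base, activation delay, t_d0).

    The first-division base is truncated at ``t_min`` by redraw; in the
    activation variants an independent untruncated activation delay is drawn
    (zero otherwise).  The realized first-division time is base + delay, but
    only the base is heritable.  The death time is untruncated and, unless
    ``death_clock_includes_activation``, runs from t = 0.
    """
    specs = _clock_specs(config)
    base = sample_lognormal_min_redraw(specs["mp"], config.t_min, rng)
    activation = 0.0
    if config.has_activation:
        activation = float(sample_lognormal(specs["a"], None, rng))
    t_d0 = float(sample_lognormal(specs["md"], None, rng))
    if config.has_activation and config.death_clock_includes_activation:
        t_d0 += activation
    return base, activation, t_d0


def draw_initial_times(
    config: ModelConfig, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw one naive cell's realized (t_p0, t_d0); see draw_initial_state."""
    base, activation, t_d0 = draw_initial_state(config, rng)
    return base + activation, t_d0


def resolve_fate(
    cell: CellRecord, horizon: float, destiny: float | None = None
) -> tuple[str, float]:
    """Resolve the divide-vs-die race for one cell; ties go to division.

    A destiny-blocked cell (generation + 1 > destiny) is quiescent and
    persists to the horizon without dying.
    """
    if destiny is not None and cell.generation + 1 > destiny:
        return "quiescent", horizon
    if cell.t_p <= cell.t_d:
        if cell.birth_time + cell.t_p <= horizon:
            return "divided", cell.birth_time + cell.t_p
    elif cell.birth_time + cell.t_d <= horizon:
        return "died", cell.birth_time + cell.t_d
    return "alive_at_horizon", horizon


def spawn_daughters(
    mother: CellRecord,
    config: ModelConfig,
    rng: np.random.Generator,
    next_id: int,
) -> tuple[CellRecord, CellRecord]:
    """Create a divided mother's two daughters.

    One shared division base (redrawn while below ``t_min``), independent
    per-daughter ``N(1, v_e)`` factors, independent per-daughter death
    factors, and marker inheritance.
    """
    if mother.fate != "divided":
        raise ValueError(f"cannot spawn daughters from a cell with fate {mother.fate!r}")
    specs = _clock_specs(config)
    heritable = mother.t_p_base if mother.t_p_base is not None else mother.t_p
    base = heritable * float(sample_lognormal(specs["p"], None, rng))
    redraws = 0
    while base < config.t_min:
        redraws += 1
        if redraws > 10_000:
            raise RuntimeError("division-base redraw cap exceeded")
        base = heritable * float(sample_lognormal(specs["p"], None, rng))
    eps = gaussian_factor(1.0, config.v_e, rng, n=2)
    dfac = sample_lognormal(specs["d"], 2, rng)
    m1, m2 = inherit_markers(mother.markers, rng, config.markers)
    daughters = []
    for j, markers in enumerate((m1, m2)):
        daughters.append(
            CellRecord(
                cell_id=next_id + j,
                family_id=mother.family_id,
                parent_id=mother.cell_id,
                generation=mother.generation + 1,
                birth_time=float(mother.end_time),
                t_p=base * float(eps[j]),
                t_d=mother.t_d * float(dfac[j]),
                markers=markers,
            )
        )
    return daughters[0], daughters[1]


def draw_division_destiny(config: ModelConfig, rng: np.random.Generator) -> float:
    """One family's continuous division destiny D_f (log-space lognormal)."""
    spec = LognormalSpec(config.mu_div, config.v_div, config.destiny_parameterization)
    return float(sample_lognormal(spec, None, rng))


# --------------------------------------------------------------------------
# population container


@dataclass
class Population:
    """Complete record of one simulated run: every cell ever created."""

    config: ModelConfig
    cells: pd.DataFrame
    destinies: np.ndarray | None = None

    @property
    def n_created(self) -> int:
        return len(self.cells)

    def alive_mask(self, at: float) -> np.ndarray:
        """Boolean mask over ``cells`` of cells alive at time ``at``.

        Alive means born at or before ``at`` and not yet divided or dead;
        persistent cells (alive_at_horizon / quiescent) count as alive at the
        horizon itself.
        """
        horizon = self.config.horizon
        if not 0 <= at <= horizon:
            raise ValueError(f"at={at} outside [0, {horizon}]")
        birth = self.cells["birth_time"].to_numpy()
        end = self.cells["end_time"].to_numpy()
        fate = self.cells["fate"].to_numpy()
        persistent = (fate == "alive_at_horizon") | (fate == "quiescent")
        return (birth <= at) & ((at < end) | ((at == end) & persistent))

    def n_alive(self, at: float) -> int:
        return int(self.alive_mask(at).sum())

    def alive(self, at: float) -> pd.DataFrame:
        return self.cells[self.alive_mask(at)]


# --------------------------------------------------------------------------
# vectorized engine


def simulate(config: ModelConfig) -> Population:
    """Run the branching process to the horizon; returns every cell created.

    Processes cells generation by generation (cells never interact, so the
    within-generation order only fixes the random-draw order, documented in
    the module docstring).  Raises :class:`PopulationExplosionError` when the
    total cell count would exceed ``config.max_cells``.
    """
    rng = np.random.default_rng(config.seed)
    specs = _clock_specs(config)
    loc_p, scale_p = specs["p"].log_params()
    loc_d, scale_d = specs["d"].log_params()
    mk = config.markers
    n0 = config.n_naive
    horizon = config.horizon

    destinies = None
    if config.has_destiny:
        destiny_rng = np.random.default_rng([config.seed, 1])
        destinies = sample_lognormal(specs["div"], n0, destiny_rng)

    # generation 0: the heritable division base excludes the activation delay
    base0 = sample_lognormal_min_redraw_vec(specs["mp"], config.t_min, n0, rng)
    activation = None
    t_p0 = base0
    if config.has_activation:
        activation = sample_lognormal(specs["a"], n0, rng)
        t_p0 = base0 + activation
    t_d0 = sample_lognormal(specs["md"], n0, rng)
    if config.has_activation and config.death_clock_includes_activation:
        t_d0 = t_d0 + activation
    cd62l = gaussian_factor(mk.init_mean_cd62l, mk.init_sd, rng, n=n0)
    cd27 = gaussian_factor(mk.init_mean_cd27, mk.init_sd, rng, n=n0)
    klrg1 = gaussian_factor(mk.init_mean_klrg1, mk.init_sd, rng, n=n0)

    gen = {
        "cell_id": np.arange(n0, dtype=np.int64),
        "family_id": np.arange(n0, dtype=np.int64),
        "parent_id": np.full(n0, -1, dtype=np.int64),
        "birth_time": np.zeros(n0),
        "t_p": t_p0,
        "t_p_base": base0,
        "t_d": t_d0,
        "cd62l": cd62l,
        "cd27": cd27,
        "klrg1": klrg1,
    }

    chunks: list[dict[str, np.ndarray]] = []
    total = n0
    g = 0
    while True:
        n = gen["cell_id"].size
        birth, t_p, t_d = gen["birth_time"], gen["t_p"], gen["t_d"]

        quiescent = np.zeros(n, dtype=bool)
        if destinies is not None:
            quiescent = (g + 1) > destinies[gen["family_id"]]
        racing = ~quiescent
        div = racing & (t_p <= t_d) & (birth + t_p <= horizon)
        die = racing & (t_d < t_p) & (birth + t_d <= horizon)

        fate = np.full(n, ALIVE, dtype=np.int8)
        fate[quiescent] = QUIESCENT
        fate[div] = DIVIDED
        fate[die] = DIED
        end = np.full(n, horizon, dtype=float)
        end[div] = birth[div] + t_p[div]
        end[die] = birth[die] + t_d[die]

        chunk = dict(gen)
        chunk.pop("t_p_base")
        chunk["generation"] = np.full(n, g, dtype=np.int64)
        chunk["fate"] = fate
        chunk["end_time"] = end
        chunks.append(chunk)

        n_div = int(div.sum())
        logger.info(
            "generation %d: %d cells, %d divided, %d died, %d quiescent, %d alive at horizon",
            g, n, n_div, int(die.sum()), int(quiescent.sum()), int((fate == ALIVE).sum()),
        )
        if n_div == 0:
            break
        total += 2 * n_div
        if total > config.max_cells:
            raise PopulationExplosionError(g + 1, total, config.max_cells)

        # phase 1: shared division bases, with pass-based t_min redraws
        m_tp = gen["t_p_base"][div]
        base = m_tp * rng.lognormal(loc_p, scale_p, size=n_div)
        offenders = np.flatnonzero(base < config.t_min)
        passes = 0
        while offenders.size:
            passes += 1
            if passes > 10_000:
                raise RuntimeError("division-base redraw cap exceeded")
            base[offenders] = m_tp[offenders] * rng.lognormal(
                loc_p, scale_p, size=offenders.size
            )
            offenders = offenders[base[offenders] < config.t_min]
        # phase 2: per-daughter division noise
        eps = np.maximum(rng.normal(1.0, config.v_e, size=(n_div, 2)), 0.0)
        tp_d = (base[:, None] * eps).ravel()
        # phase 3: per-daughter death factors
        dfac = rng.lognormal(loc_d, scale_d, size=(n_div, 2))
        td_d = (t_d[div][:, None] * dfac).ravel()
        # phases 4-6: marker inheritance
        f62 = np.maximum(rng.normal(mk.cd62l_factor_mean, mk.cd62l_factor_sd, (n_div, 2)), 0.0)
        f27 = np.maximum(rng.normal(mk.cd27_factor_mean, mk.cd27_factor_sd, (n_div, 2)), 0.0)
        fkl = np.maximum(rng.normal(mk.klrg1_factor_mean, mk.klrg1_factor_sd, (n_div, 2)), 0.0)

        first_id = chunks[-1]["cell_id"][-1] + 1 if g else n0
        gen = {
            "cell_id": np.arange(first_id, first_id + 2 * n_div, dtype=np.int64),
            "family_id": np.repeat(gen["family_id"][div], 2),
            "parent_id": np.repeat(gen["cell_id"][div], 2),
            "birth_time": np.repeat(end[div], 2),
            "t_p": tp_d,
            "t_p_base": tp_d,
            "t_d": td_d,
            "cd62l": (gen["cd62l"][div][:, None] * f62).ravel(),
            "cd27": (gen["cd27"][div][:, None] * f27).ravel(),
            "klrg1": (gen["klrg1"][div][:, None] * fkl).ravel(),
        }
        g += 1

    columns = [
        "cell_id", "family_id", "parent_id", "generation",
        "birth_time", "t_p", "t_d", "fate", "end_time",
        "cd62l", "cd27", "klrg1",
    ]
    data = {c: np.concatenate([ch[c] for ch in chunks]) for c in columns if c != "fate"}
    fate_codes = np.concatenate([ch["fate"] for ch in chunks])
    df = pd.DataFrame(data)
    df["fate"] = pd.Categorical.from_codes(fate_codes, categories=list(FATES))
    df = df[columns]
    return Population(config=config, cells=df, destinies=destinies)
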