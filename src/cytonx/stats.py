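"""Population- and single-cell-level summary statistics.

Every statistic is a pure function of the cell table (plus the config), so
anything computed here from an in-memory :class:`~cytonx.lineage.Population`
can be recomputed from a written cell table.

Conventions
-----------
* "Day d" snapshot = the state at t = 24*(d-1) hours (cells alive at the
  start of the day); family sizes "on day 8" = cells alive at the horizon.
* Zero-size families (the founder died without surviving progeny) stay in
  the denominator of the disparity statistic — they were naive founders —
  but are excluded pairwise from marker–size correlations, where their
  positive fractions are undefined.
* A divider's subset is gated on its own marker levels at the division
  instant; its "day" is the day containing the division event.
* Quantiles use linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .lineage import Population
from .markers import SUBSET_LABELS, gate_subsets

__all__ = [
    "CorrelationResult",
    "cumulative_share_curve",
    "division_death_times_by_generation",
    "division_events",
    "expression_distributions",
    "family_sizes",
    "marker_summary_by_family",
    "proliferation_rates",
    "spearman_with_ci",
    "subset_counts_by_day",
]

_QUANTILES = (0.05, 0.25, 0.5, 0.75, 0.95)


def family_sizes(pop: Population, at: float) -> pd.Series:
    """Number of cells of each family alive at time ``at``.

    Zero-size families are retained (indexed 0..n_naive-1).
    """
    alive = pop.alive_mask(at)
    fam = pop.cells["family_id"].to_numpy()[alive]
    counts = np.bincount(fam, minlength=pop.config.n_naive)
    return pd.Series(counts, index=pd.RangeIndex(pop.config.n_naive, name="family_id"),
                     name="size")


def cumulative_share_curve(sizes: np.ndarray | pd.Series) -> tuple[pd.DataFrame, float]:
    """Family-size disparity curve and the fraction-for-half statistic.

    Families are sorted by size descending; the curve gives, for the largest
    k families, their cumulative cell count and cumulative share of all
    cells.  ``fraction_for_half`` is the percentage of families (zero-size
    families included in the denominator) needed to reach half of all cells.
    """
    sizes = np.asarray(sizes)
    total = sizes.sum()
    if total <= 0:
        raise ValueError("all family sizes are zero")
    ordered = np.sort(sizes)[::-1]
    cum = np.cumsum(ordered)
    share = cum / total
    k = int(np.searchsorted(share, 0.5)) + 1  # smallest k with share >= 0.5
    fraction_for_half = 100.0 * k / sizes.size
    curve = pd.DataFrame(
        {
            "rank": np.arange(1, sizes.size + 1),
            "family_pct": 100.0 * np.arange(1, sizes.size + 1) / sizes.size,
            "size": ordered,
            "cumulative_cells": cum,
            "cumulative_share": share,
        }
    )
    return curve, fraction_for_half


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation with a 95% CI and t-approximation p-value."""

    rho: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def spearman_with_ci(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    ci_method: str = "fisher",
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> CorrelationResult:
    """Spearman rho (average ranks for ties) with 95% CI.

    Pairs with a missing value are dropped.  The p-value uses the Student-t
    approximation t = rho*sqrt((n-2)/(1-rho^2)); the CI uses the Fisher
    z-transform with SE = 1/sqrt(n-3) (``ci_method="bootstrap"`` resamples
    pairs instead).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 finite pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant input vector")
    rho = float(sps.spearmanr(x, y).statistic)

    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    p = max(p, np.finfo(float).tiny)

    if ci_method == "fisher":
        z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
        hw = sps.norm.ppf(0.975) / np.sqrt(n - 3)
        ci_low, ci_high = float(np.tanh(z - hw)), float(np.tanh(z + hw))
    elif ci_method == "bootstrap":
        rng = rng or np.random.default_rng(0)
        idx = rng.integers(0, n, size=(n_boot, n))
        boots = np.array([sps.spearmanr(x[i], y[i]).statistic for i in idx])
        ci_low, ci_high = (float(q) for q in np.nanquantile(boots, [0.025, 0.975]))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return CorrelationResult(rho=rho, ci_low=ci_low, ci_high=ci_high, p_value=p, n=n)


def marker_summary_by_family(pop: Population, at: float) -> pd.DataFrame:
    """Per-family size, marker-positive fractions and CD62L+ count at ``at``.

    Zero-size families get NaN fractions (excluded pairwise downstream).
    """
    thr = pop.config.markers.thresholds
    alive = pop.cells[pop.alive_mask(at)]
    fam = alive["family_id"].to_numpy()
    n_fam = pop.config.n_naive
    size = np.bincount(fam, minlength=n_fam).astype(float)
    pos62 = np.bincount(fam, weights=(alive["cd62l"].to_numpy() >= thr.cd62l), minlength=n_fam)
    pos27 = np.bincount(fam, weights=(alive["cd27"].to_numpy() >= thr.cd27), minlength=n_fam)
    poskl = np.bincount(fam, weights=(alive["klrg1"].to_numpy() >= thr.klrg1), minlength=n_fam)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = pd.DataFrame(
            {
                "family_id": np.arange(n_fam),
                "size": size.astype(int),
                "frac_cd62l_pos": np.where(size > 0, pos62 / size, np.nan),
                "frac_cd27_pos": np.where(size > 0, pos27 / size, np.nan),
                "frac_klrg1_pos": np.where(size > 0, poskl / size, np.nan),
                "n_cd62l_pos": pos62.astype(int),
            }
        )
    return out


def _day_snapshots(pop: Population) -> list[tuple[int, float]]:
    n_days = int(pop.config.horizon // 24) or 1
    return [(d, 24.0 * (d - 1)) for d in range(1, n_days + 1)]


def _stat_rows(values: np.ndarray, keys: dict) -> list[dict]:
    rows = []
    if values.size:
        qs = np.quantile(values, _QUANTILES)
        stats = dict(zip([f"q{int(q * 100)}" for q in _QUANTILES], qs))
        stats["mean"] = values.mean()
        stats["n"] = values.size
    else:
        stats = {f"q{int(q * 100)}": np.nan for q in _QUANTILES}
        stats.update(mean=np.nan, n=0)
    for stat, value in stats.items():
        rows.append({**keys, "stat": stat, "value": value})
    return rows


def expression_distributions(pop: Population, by: str = "day") -> pd.DataFrame:
    """Relative marker expression (level / threshold) distributions.

    ``by="day"``: over cells alive at the start of each day.
    ``by="generation"``: over all cells ever created in each generation.
    Long format: one row per (key, marker, stat), stats = quantiles
    5/25/50/75/95, mean and n.
    """
    thr = pop.config.markers.thresholds
    rel = {
        "cd62l": pop.cells["cd62l"].to_numpy() / thr.cd62l,
        "cd27": pop.cells["cd27"].to_numpy() / thr.cd27,
        "klrg1": pop.cells["klrg1"].to_numpy() / thr.klrg1,
    }
    rows: list[dict] = []
    if by == "day":
        for day, t in _day_snapshots(pop):
            mask = pop.alive_mask(t)
            for marker, values in rel.items():
                rows += _stat_rows(values[mask], {"day": day, "marker": marker})
    elif by == "generation":
        gen = pop.cells["generation"].to_numpy()
        for g in range(int(gen.max()) + 1):
            mask = gen == g
            for marker, values in rel.items():
                rows += _stat_rows(values[mask], {"generation": g, "marker": marker})
    else:
        raise ValueError(f"by must be 'day' or 'generation', got {by!r}")
    return pd.DataFrame(rows)


def subset_counts_by_day(pop: Population) -> pd.DataFrame:
    """Counts of Tcm/Tem/Teff/other among cells alive at each day start."""
    thr = pop.config.markers.thresholds
    rows = []
    for day, t in _day_snapshots(pop):
        alive = pop.cells[pop.alive_mask(t)]
        labels = gate_subsets(alive["cd62l"].to_numpy(), alive["cd27"].to_numpy(), thr)
        for subset in SUBSET_LABELS:
            rows.append({"day": day, "subset": subset,
                         "count": int((labels == subset).sum())})
    return pd.DataFrame(rows)


def division_events(pop: Population) -> pd.DataFrame:
    """One row per division: generation, day, rate = 1/t_p, and the divider's
    subset gated on its own markers at the division instant."""
    thr = pop.config.markers.thresholds
    div = pop.cells[pop.cells["fate"] == "divided"]
    n_days = int(pop.config.horizon // 24) or 1
    day = np.minimum(div["end_time"].to_numpy() // 24, n_days - 1).astype(int) + 1
    return pd.DataFrame(
        {
            "cell_id": div["cell_id"].to_numpy(),
            "family_id": div["family_id"].to_numpy(),
            "generation": div["generation"].to_numpy(),
            "day": day,
            "t_p": div["t_p"].to_numpy(),
            "rate": 1.0 / div["t_p"].to_numpy(),
            "subset": gate_subsets(div["cd62l"].to_numpy(), div["cd27"].to_numpy(), thr),
        }
    )


def proliferation_rates(pop: Population, by: str = "subset_day") -> pd.DataFrame:
    """Distribution of proliferation rates 1/t_p among cells that divided.

    ``by="subset_day"`` groups by the divider's gated subset and the day of
    its division event; ``by="generation"`` groups by the divider's
    generation.  Quiescent and dying cells never contribute.
    """
    events = division_events(pop)
    rows: list[dict] = []
    if by == "subset_day":
        for (subset, day), grp in events.groupby(["subset", "day"], observed=True):
            rows += _stat_rows(grp["rate"].to_numpy(), {"subset": subset, "day": day})
    elif by == "generation":
        for g, grp in events.groupby("generation"):
            rows += _stat_rows(grp["rate"].to_numpy(), {"generation": int(g)})
    else:
        raise ValueError(f"by must be 'subset_day' or 'generation', got {by!r}")
    return pd.DataFrame(rows)


def division_death_times_by_generation(pop: Population) -> pd.DataFrame:
    """Per generation, the distributions of drawn division times among cells
    that divided and death times among cells that died."""
    cells = pop.cells
    rows: list[dict] = []
    for g, grp in cells.groupby("generation"):
        rows += _stat_rows(
            grp.loc[grp["fate"] == "divided", "t_p"].to_numpy(),
            {"generation": int(g), "variable": "division_time"},
        )
        rows += _stat_rows(
            grp.loc[grp["fate"] == "died", "t_d"].to_numpy(),
            {"generation": int(g), "variable": "death_time"},
        )
    return pd.DataFrame(rows)
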