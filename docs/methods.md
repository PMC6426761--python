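# Methods

## The stochastic-inheritance model

`cytonx` simulates clonal expansion of CD8⁺ T cells as a branching process
in which each cell holds two independent stochastic timers, following the
Cyton picture: a division clock `t_p` and a death clock `t_d`, both drawn at
birth. Whichever fires first decides the fate (a tie divides — a
measure-zero event fixed for determinism). A dividing mother produces
exactly two daughters at her division time. Cells do not interact: there is
no antigen dynamics, no competition, no contraction phase — the model covers
the first 8 days (192 h) of expansion only.

Inheritance makes kinetics heritable. The two daughters share one division
base `t_p(i) = t_p(i−1) × L(μ_p, v_p)` (redrawn while below `t_min`), each
perturbed by an independent `N(1, v_e)` factor, so sisters' division times
are strongly correlated. Death clocks are inherited per daughter,
`t_d(i) = t_d(i−1) × L(μ_d, σ_d)`, independently of the division side. With
`μ_p = 1.25 > 1` and `μ_d = 0.99 < 1` the mean division time rises and the
mean death time falls with generation, so lineages eventually run into
death pressure; the only reason some families grow very large is that
kinetic noise is heritable — fast chains stay fast, and selection among
lineages does the rest. This emergent selection is visible as a
non-monotone trend in the realized division times of dividing cells: the
per-generation mean rises to a peak (around generation 8–10 at the
defaults) and then *falls*, because beyond the crossing point only
fast-dividing cells escape death.

Surface markers (CD62L, CD27, KLRG1) are pure passengers: levels change
only at division, each daughter's level being the mother's times an
independent Gaussian factor, and never influence kinetics. Positivity is
boundary-inclusive (level ≥ threshold). The conventional subsets are gated
from two markers only (Tcm = CD62L⁺CD27⁺, Tem = CD62L⁻CD27⁺,
Teff = CD62L⁻CD27⁻); the undefined CD62L⁺CD27⁻ quadrant is reported as
`other`, never merged.

### Variants

* **basic** — all naive cells are activated at t = 0.
* **heterogeneous_activation** — each naive cell's first division is delayed
  by an independent `L(μ_a, v_a)` activation time. The delay postpones only
  the first division and is *not* heritable: daughters chain from the
  lognormal base, not from base + delay (inheriting the ~57 h delay would
  throttle every descendant's division clock and the variant would collapse
  to a few hundred cells). As the death equation is written, the naive
  cell's death clock still runs from t = 0, so most founders die before
  activating; the switch `death_clock_includes_activation` starts the death
  clock at activation instead, which keeps essentially all 1,000 families
  alive. The default is the as-written rule; the switch changes the
  family-count structure (≈220 vs ≈1,000 surviving families) and roughly
  triples the families-for-half statistic.
* **division_destiny** — extends the activation variant: each family draws a
  continuous destiny `D_f = exp(N(μ_div, v_div))`; a cell of generation g
  may divide only while `g + 1 ≤ D_f`. Destiny-blocked cells become
  quiescent: they neither divide nor die and are counted as alive through
  the horizon (and excluded from division-time statistics). `D_f` is kept
  continuous — the draw is continuous and rounding would shift its stated
  mean of ~8 generations.

## Parameters and spread conventions

Defaults (per `ModelConfig`): `n_naive = 1000`, `horizon = 192 h`,
`μ_mp = 4.5 h`, `v_mp = 0.2·μ_mp`, `μ_p = 1.25`, `v_p = 0.05·μ_p`,
`t_min = 4 h`, `v_e = 0.02`, `μ_md = 40 h`, `σ_md = 0.2·μ_md`, `μ_d = 0.99`,
`σ_d = 0.05·μ_d`, `μ_a = 57 h`, `v_a = 29 h`, `μ_div = 1.73`,
`v_div = 0.83`. The spread ratios stay in force when a mean is overridden,
unless the spread is set explicitly.

How the second parameters are read is a modeling decision, because the
mixture of `v` and `σ` symbols is not self-consistent; the package fixes it
as follows and exposes switches for each choice:

* **Lognormal waiting-time spreads** (`v_mp`, `v_p`, `σ_md`, `σ_d`) are
  natural-scale **variances** (`kinetic_spreads="variance"`, the default;
  `"sd"` reads them as standard deviations). The variance reading is what
  gives the model its characteristic regime: per-division factor dispersion
  of ~20% lets rare lineages stay fast for 15–25 generations, producing
  day-8 populations > 10⁶ cells, maximum families near 10⁵ cells against a
  median near 10³, and the strong positive KLRG1-fraction-vs-size rank
  correlation. Under the SD reading the factor CV is 5%, no lineage passes
  ~13 generations, the largest family stays below ~3×10³ and none of those
  statistics is reachable.
* **Gaussian noise** (`v_e`, the marker factors, the initial marker levels)
  uses **standard deviations**. This is validated independently: with
  factor SDs of 0.15, the KLRG1 and CD27 fraction-vs-size correlations land
  at ≈ +0.8 and ≈ −0.1 at full scale, matching the regime the model is
  meant to produce; variance-read marker noise (SD ≈ 0.39) washes the KLRG1
  correlation down to ≈ 0.45.
* **Activation** `v_a = 29 h` is a standard deviation
  (`activation_spread="sd"`): the value is quoted from experimental
  first-division-time measurements as a mean ± SD pair, and the variant
  exists precisely to inject large (CV ≈ 0.5) activation heterogeneity.
* **Destiny** `(μ_div, v_div)` is log-space (location, scale):
  `exp(1.73 + 0.83²/2) ≈ 7.96`, the intended ~8-generation mean destiny; a
  natural-scale reading of 1.73 would be meaningless.

## Randomness and reproducibility

One `numpy` PCG64 generator, seeded with the config seed, drives the whole
run. Draws are consumed generation-major in a documented phase order
(division bases with pass-based truncation redraws, per-daughter division
noise, death factors, then CD62L/CD27/KLRG1 factor blocks, each `(n, 2)`
row-major; generation 0: bases, activation, death times, marker
initializations). The test suite contains a per-cell reference
implementation that consumes the stream in the same order and must
reproduce the engine's cell table bit-for-bit.

Division destinies are drawn from an auxiliary generator seeded from
`(seed, 1)`, so the main event stream is identical across variants at the
same seed; setting an unreachably high destiny reproduces the activation
variant's table exactly, and destiny-vs-no-destiny comparisons at one seed
are meaningfully coupled.

Two reproducibility caveats. Truncation-by-redraw caps at 10,000 attempts
and then raises, turning a pathological configuration (essentially all mass
below `t_min`) into a diagnosable error. And the horizon acts as an
observation window only in distribution: because the per-generation draw
blocks cover cells that actually divide, and that set depends on the
horizon, two runs with different horizons agree at a common time in law but
not bitwise (they do agree exactly in the zero-noise limit, which is the
form the test suite checks).

## Summary statistics

All statistics are pure functions of the cell table (plus thresholds), so a
written table can be re-summarized without re-simulation. Conventions:
"day d" is the snapshot at t = 24(d−1) h; day-8 family sizes are cells
alive at 192 h; zero-size families stay in the denominator of the
families-for-half statistic (their founders were naive cells) but are
excluded pairwise from marker–size correlations (their fractions are
undefined); a divider's subset is gated on its own levels at the division
instant and its day is the day containing that instant, with "day 5
onwards" meaning events in [96 h, 192 h]; per-generation expression
distributions pool all cells ever created in a generation (a switchable
choice — the day-based tables use alive-at-snapshot cells); quantiles use
linear interpolation. Spearman correlations use average ranks, a Student-t
p-value `t = ρ√((n−2)/(1−ρ²))`, and a Fisher-z 95% CI with
`SE = 1/√(n−3)` (a pair-resampling bootstrap CI is available).

## What the simulation does and does not emulate

The generator reproduces the *statistical* signatures of clonal expansion:
heavy-tailed family sizes, division-linked marker drift, emergent kinetic
selection. It does not model antigen load, niche competition, migration,
the contraction/memory phase, continuous (division-independent) marker
dynamics, or transcriptional states; marker levels are arbitrary units with
arbitrary thresholds. Agreement of a statistic here therefore shows that
stochastic inheritance *suffices* for that pattern — not that real T cells
lack fate programs.

## Known limitations

* CD62L sits awkwardly in the marker scheme: its threshold (97) lies less
  than one mean division's decline (5%) below the initial level (100), so
  with the stated factor noise (SD 0.05) expected retention collapses after
  a couple of divisions, per-family CD62L⁺ fractions are near zero for
  every family that expanded, and their rank correlation with family size
  is weak and threshold-sensitive — far weaker than the corresponding KLRG1
  correlation, whose threshold sits mid-range of the generation
  distribution. Larger factor noise raises retention but caps the
  correlation around −0.4 because shared ancestral draws dominate
  between-family variance.
* Family-size tails are sensitive to the interaction of the `t_min` floor
  with the division-factor dispersion; configurations with substantially
  larger `v_p` can produce runaway lineages that divide near the floor
  indefinitely (the `max_cells` cap, default 5×10⁷, converts this into an
  error naming the generation reached).
* Memory use is dominated by the full cell table (~12 numeric columns per
  cell ever created; a default basic run holds ~10⁷ records, ~1 GB).
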