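"""Model configuration: variants, kinetic parameters, marker parameters.

Defaults are the simulator's reference parameter set: a mean first-division
time of 4.5 h (SD 0.2x), a per-division division-time multiplier of mean 1.25
(SD 0.05x), a 4 h minimum division time enforced by redraw, daughter noise
N(1, 0.02), a mean initial death time of 40 h (SD 0.2x) decaying by a factor
of mean 0.99 (SD 0.05x) per division, an activation delay of mean 57 h
(SD 29 h) in the heterogeneous-activation and division-destiny variants, and a
log-space lognormal(1.73, 0.83) division destiny (natural-scale mean ~7.96
generations).

The spread parameters ``v_mp``, ``v_p``, ``sigma_md`` and ``sigma_d`` default
to fixed ratios of their means (0.2, 0.05, 0.2, 0.05 respectively); leaving
them unset in a config file keeps the ratio rule even when the mean is
overridden.

Spread conventions
------------------
The lognormal waiting-time spreads (``v_mp``, ``v_p``, ``sigma_md``,
``sigma_d``) are natural-scale *variances* by default
(``kinetic_spreads="variance"``); set ``kinetic_spreads="sd"`` to read them
as standard deviations instead.  The variance convention is the reference
one: it is what produces the model's characteristic deep lineage trees
(20+ generations), 10^5-cell families and >10^6-cell day-8 populations —
under the SD reading the per-division dispersion is too small for any of
those to arise.  All Gaussian noise parameters (``v_e``, marker factors) are
standard deviations, the activation spread ``v_a`` is a natural-scale SD,
and the division-destiny pair (``mu_div``, ``v_div``) is log-space
(location, scale).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal

__all__ = [
    "MarkerParams",
    "MarkerThresholds",
    "ModelConfig",
    "VARIANTS",
    "load_config",
]

VARIANTS = ("basic", "heterogeneous_activation", "division_destiny")

#: CLI-friendly aliases for variant names.
VARIANT_ALIASES = {
    "basic": "basic",
    "activation": "heterogeneous_activation",
    "heterogeneous_activation": "heterogeneous_activation",
    "destiny": "division_destiny",
    "division_destiny": "division_destiny",
}


@dataclass(frozen=True)
class MarkerThresholds:
    """Positivity thresholds in the same arbitrary units as the levels.

    A cell is positive for a marker when its level is >= the threshold
    (boundary inclusive)."""

    cd62l: float = 97.0
    cd27: float = 90.0
    klrg1: float = 80.0

    def __post_init__(self) -> None:
        for name in ("cd62l", "cd27", "klrg1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass(frozen=True)
class MarkerParams:
    """Initialization and inheritance parameters for the three surface markers.

    Naive cells start CD62L-high (~100), CD27-high (~100) and KLRG1-low (~10).
    On each division every daughter's level is the mother's level times an
    independent Gaussian factor: CD62L tends to drop 5% per division, CD27
    drifts without trend, KLRG1 tends to rise 15% per division.
    """

    init_mean_cd62l: float = 100.0
    init_mean_cd27: float = 100.0
    init_mean_klrg1: float = 10.0
    init_sd: float = 0.01
    cd62l_factor_mean: float = 0.95
    cd62l_factor_sd: float = 0.05
    cd27_factor_mean: float = 1.0
    cd27_factor_sd: float = 0.15
    klrg1_factor_mean: float = 1.15
    klrg1_factor_sd: float = 0.15
    thresholds: MarkerThresholds = field(default_factory=MarkerThresholds)


@dataclass(frozen=True)
class ModelConfig:
    """Full configuration of one simulation run.

    Spread parameters left as ``None`` are derived from their means by the
    default ratio rules (see module docstring).
    """

    variant: Literal["basic", "heterogeneous_activation", "division_destiny"] = "basic"
    n_naive: int = 1000
    horizon: float = 192.0  # hours; 8 days
    seed: int = 0

    # division clock
    mu_mp: float = 4.5  # mean first-division time, hours
    v_mp: float | None = None  # SD, hours; default 0.2 * mu_mp
    mu_p: float = 1.25  # per-division multiplier on the division time
    v_p: float | None = None  # SD; default 0.05 * mu_p
    t_min: float = 4.0  # minimum division time, hours (enforced by redraw)
    v_e: float = 0.02  # SD of the per-daughter N(1, v_e) noise

    # death clock
    mu_md: float = 40.0  # mean initial death time, hours
    sigma_md: float | None = None  # SD, hours; default 0.2 * mu_md
    mu_d: float = 0.99  # per-division multiplier on the death time
    sigma_d: float | None = None  # SD; default 0.05 * mu_d

    # activation delay (heterogeneous_activation and division_destiny variants)
    mu_a: float = 57.0  # mean activation time, hours
    v_a: float = 29.0  # SD, hours
    # If true, the activation delay also postpones the naive cell's death
    # clock (alternative rule; by default activation delays only the first
    # division and the death clock runs from t = 0).
    death_clock_includes_activation: bool = False

    # division destiny (division_destiny variant)
    mu_div: float = 1.73
    v_div: float = 0.83

    # spread-parameter conventions (see module docstring)
    kinetic_spreads: Literal["variance", "sd"] = "variance"
    activation_spread: Literal["sd", "variance"] = "sd"
    destiny_parameterization: Literal["log_space", "natural_moments"] = "log_space"

    markers: MarkerParams = field(default_factory=MarkerParams)

    max_cells: int = 50_000_000  # hard cap on total cell records

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.n_naive < 1:
            raise ValueError("n_naive must be >= 1")
        if self.horizon < 0:
            raise ValueError("horizon must be non-negative")
        for name in ("mu_mp", "mu_p", "t_min", "mu_md", "mu_d", "mu_a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"time parameter {name} must be positive")
        for name in ("v_mp", "v_p", "sigma_md", "sigma_d"):
            val = getattr(self, name)
            if val is not None and val < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.v_e < 0 or self.v_a < 0 or self.v_div < 0:
            raise ValueError("spread parameters must be non-negative")
        if self.kinetic_spreads not in ("variance", "sd"):
            raise ValueError(f"kinetic_spreads must be 'variance' or 'sd', got {self.kinetic_spreads!r}")
        if self.activation_spread not in ("sd", "variance"):
            raise ValueError(f"activation_spread must be 'sd' or 'variance', got {self.activation_spread!r}")
        if self.destiny_parameterization not in ("log_space", "natural_moments"):
            raise ValueError(f"invalid destiny_parameterization {self.destiny_parameterization!r}")
        if self.max_cells < self.n_naive:
            raise ValueError("max_cells must be at least n_naive")
        if self.mu_p <= 1:
            warnings.warn(
                f"mu_p = {self.mu_p} <= 1: division times will not tend to "
                "increase with generation",
                stacklevel=2,
            )
        if self.mu_d >= 1:
            warnings.warn(
                f"mu_d = {self.mu_d} >= 1: death times will not tend to "
                "shorten with generation",
                stacklevel=2,
            )

    # ---- derived spreads (ratio rules + convention) ------------------------
    def _kinetic_sd(self, value: float) -> float:
        return float(value**0.5) if self.kinetic_spreads == "variance" else value

    @property
    def v_mp_eff(self) -> float:
        """First-division spread as an SD, in hours."""
        return self._kinetic_sd(0.2 * self.mu_mp if self.v_mp is None else self.v_mp)

    @property
    def v_p_eff(self) -> float:
        """Division-factor spread as an SD (dimensionless)."""
        return self._kinetic_sd(0.05 * self.mu_p if self.v_p is None else self.v_p)

    @property
    def sigma_md_eff(self) -> float:
        """Initial death-time spread as an SD, in hours."""
        return self._kinetic_sd(0.2 * self.mu_md if self.sigma_md is None else self.sigma_md)

    @property
    def sigma_d_eff(self) -> float:
        """Death-factor spread as an SD (dimensionless)."""
        return self._kinetic_sd(0.05 * self.mu_d if self.sigma_d is None else self.sigma_d)

    @property
    def v_a_eff(self) -> float:
        """Activation-delay spread as an SD, in hours."""
        return float(self.v_a**0.5) if self.activation_spread == "variance" else self.v_a

    @property
    def has_activation(self) -> bool:
        return self.variant in ("heterogeneous_activation", "division_destiny")

    @property
    def has_destiny(self) -> bool:
        return self.variant == "division_destiny"

    def replace(self, **changes: Any) -> "ModelConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        """JSON-serializable flat dict (markers nested)."""
        d = dataclasses.asdict(self)
        return d


# --------------------------------------------------------------------------
# config-file loading

_CONFIG_KEYS = {f.name for f in dataclasses.fields(ModelConfig)} - {"markers"}
_MARKER_KEYS = {f.name for f in dataclasses.fields(MarkerParams)} - {"thresholds"}
_THRESHOLD_KEYS = {f.name for f in dataclasses.fields(MarkerThresholds)}


def _parse_value(raw: str) -> Any:
    """Coerce a CLI override string to bool/int/float/str."""
    low = raw.lower()
    if low in ("true", "false"):
        return low == "true"
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    return raw


def _build_config(data: dict[str, Any]) -> ModelConfig:
    data = dict(data)
    if "variant" in data:
        v = data["variant"]
        if v not in VARIANT_ALIASES:
            raise ValueError(f"unknown variant {v!r}")
        data["variant"] = VARIANT_ALIASES[v]
    marker_data = data.pop("markers", {})
    if not isinstance(marker_data, dict):
        raise ValueError("'markers' must be a table/object")
    marker_data = dict(marker_data)
    thr_data = marker_data.pop("thresholds", {})

    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    unknown = set(marker_data) - _MARKER_KEYS
    if unknown:
        raise ValueError(f"unknown marker key(s): {sorted(unknown)}")
    unknown = set(thr_data) - _THRESHOLD_KEYS
    if unknown:
        raise ValueError(f"unknown threshold key(s): {sorted(unknown)}")

    markers = MarkerParams(thresholds=MarkerThresholds(**thr_data), **marker_data)
    return ModelConfig(markers=markers, **data)


def load_config(
    path: str | Path | None = None,
    overrides: list[str] | None = None,
) -> ModelConfig:
    """Load a :class:`ModelConfig` from a JSON or TOML file plus overrides.

    Missing keys take the defaults; unknown keys are rejected by name.
    ``overrides`` are ``key=value`` strings applied last; marker parameters
    are addressed as ``markers.<name>`` and thresholds as
    ``markers.thresholds.<name>``.
    """
    data: dict[str, Any] = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".toml":
            import tomllib

            data = tomllib.loads(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ValueError("config file must contain a table/object at top level")

    for item in overrides or []:
        if "=" not in item:
            raise ValueError(f"override {item!r} is not of the form key=value")
        key, _, raw = item.partition("=")
        key = key.strip()
        value = _parse_value(raw.strip())
        parts = key.split(".")
        target = data
        for part in parts[:-1]:
            target = target.setdefault(part, {})
            if not isinstance(target, dict):
                raise ValueError(f"override {key!r} conflicts with a scalar key")
        target[parts[-1]] = value

    return _build_config(data)
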