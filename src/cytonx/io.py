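"""Cell-table and manifest I/O.

The cell table is one row per cell with a fixed header; generation-0 cells
carry ``parent_id = -1``.  CSV is the default interchange format; parquet is
used for large runs (the CLI switches automatically above 2e6 rows).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ModelConfig
from .lineage import FATES, Population

__all__ = [
    "CELL_COLUMNS",
    "RunManifest",
    "SchemaError",
    "population_from_table",
    "read_cells",
    "write_cells",
]

CELL_COLUMNS = [
    "cell_id", "family_id", "parent_id", "generation",
    "birth_time", "t_p", "t_d", "fate", "end_time",
    "cd62l", "cd27", "klrg1",
]

#: Row count above which the CLI writes parquet instead of CSV.
BINARY_THRESHOLD = 2_000_000


class SchemaError(ValueError):
    """The cell table does not conform to the documented schema."""


def write_cells(pop_or_df: Population | pd.DataFrame, path: str | Path) -> int:
    """Write a cell table as CSV (.csv) or parquet (.parquet); returns rows."""
    df = pop_or_df.cells if isinstance(pop_or_df, Population) else pop_or_df
    path = Path(path)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)
    return len(df)


def read_cells(path: str | Path) -> pd.DataFrame:
    """Read and validate a cell table written by :func:`write_cells`."""
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table is missing column(s): {missing}")
    bad_fates = set(df["fate"].unique()) - set(FATES)
    if bad_fates:
        raise SchemaError(f"unknown fate value(s): {sorted(bad_fates)}")
    df = df[CELL_COLUMNS].copy()
    for col in ("cell_id", "family_id", "parent_id", "generation"):
        df[col] = df[col].astype(np.int64)
    df["fate"] = pd.Categorical(df["fate"], categories=list(FATES))
    return df


def population_from_table(df: pd.DataFrame, config: ModelConfig) -> Population:
    """Rebuild a :class:`Population` from a cell table for re-summarization.

    Division destinies are not stored in the table, so ``destinies`` is None;
    all summary statistics are pure functions of the table and config.
    """
    n_fam = int(df["family_id"].max()) + 1 if len(df) else 0
    if n_fam != config.n_naive:
        config = config.replace(n_naive=max(n_fam, 1))
    return Population(config=config, cells=df)


@dataclass
class RunManifest:
    """Everything needed to re-run a simulation bit-identically, plus the
    files it produced."""

    config: dict
    seed: int
    version: str
    files: dict[str, dict] = field(default_factory=dict)
    wall_time_s: float | None = None

    def add_file(self, name: str, path: Path, rows: int) -> None:
        self.files[name] = {"path": str(path), "rows": rows}

    def write(self, path: str | Path) -> None:
        """Atomic write: serialize to a temp file, then rename."""
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(asdict(self), indent=2, default=str))
        tmp.replace(path)

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def start_timer() -> float:
    return time.perf_counter()
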