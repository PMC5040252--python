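"""Reading, writing and synthesising RTCA Cell-Index exports.

Impedance analysers export migration data as spreadsheets with one
table per (cell line, seeded count, independent experiment): the first
column is time in hours, the second the mean Cell Index of a
quadruplicate, the third its standard deviation.  This module parses
such tables from CSV or XLSX, averages independent experiments into a
single reference curve, and generates synthetic exports from the
simulator so that the complete pipeline can be exercised without
instrument data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .observables import CellIndexMap, Curve, migrated_cell_number, to_cell_index
from .parameters import (
    AssayGeometry,
    InitialConditions,
    ModelParameters,
    SimulationSettings,
)
from .solver import simulate

__all__ = [
    "RtcaTable",
    "read_rtca_table",
    "write_rtca_table",
    "average_replicates",
    "synthesize_experiment",
]

CSV_COLUMNS = ("time_h", "ci_mean", "ci_sd")


@dataclass
class RtcaTable:
    """One exported table: time (h), mean Cell Index, optional SD."""

    times: np.ndarray
    ci_mean: np.ndarray
    ci_sd: Optional[np.ndarray] = None
    label: str = ""
    n_replicates: Optional[int] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ci_mean = np.asarray(self.ci_mean, dtype=float)
        if self.times.shape != self.ci_mean.shape or self.times.ndim != 1:
            raise ValueError("time and mean columns must be aligned 1D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.ci_sd is not None:
            self.ci_sd = np.asarray(self.ci_sd, dtype=float)
            if self.ci_sd.shape != self.times.shape:
                raise ValueError("sd column must be aligned with time")
            if np.any(self.ci_sd < 0):
                raise ValueError("sd must be >= 0")

    @property
    def has_sd(self) -> bool:
        return self.ci_sd is not None

    def as_curve(self) -> Curve:
        return Curve(self.times, self.ci_mean, sd=self.ci_sd, label=self.label)


class RtcaFormatError(ValueError):
    """Raised when a file does not contain a parseable Cell-Index table."""


def _frame_to_table(df: pd.DataFrame, label: str) -> RtcaTable:
    if df.shape[1] < 2:
        raise RtcaFormatError(f"{label}: need at least 2 columns (time, mean CI)")
    df = df.iloc[:, :3].apply(pd.to_numeric, errors="coerce")
    good = df.iloc[:, 0].notna() & df.iloc[:, 1].notna()
    dropped = int((~good).sum())
    if dropped:
        import logging

        logging.getLogger(__name__).info(
            "%s: dropped %d non-numeric row(s)", label, dropped
        )
    df = df[good]
    if df.empty:
        raise RtcaFormatError(f"{label}: no numeric rows")
    sd = df.iloc[:, 2].to_numpy() if df.shape[1] >= 3 and df.iloc[:, 2].notna().all() else None
    return RtcaTable(
        times=df.iloc[:, 0].to_numpy(),
        ci_mean=df.iloc[:, 1].to_numpy(),
        ci_sd=sd,
        label=label,
    )


def read_rtca_table(path: str | Path, sheet: str | int | None = None) -> RtcaTable:
    """Read one Cell-Index table from a CSV file or an XLSX sheet.

    Column order is positional (time, mean, SD); the SD column is
    optional.  Rows whose time or mean cannot be parsed as numbers are
    dropped (with a logged count).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=sheet if sheet is not None else 0)
        label = f"{path.name}[{sheet if sheet is not None else 0}]"
    else:
        df = pd.read_csv(path)
        label = path.name
    return _frame_to_table(df, label)


def read_rtca_workbook(path: str | Path) -> dict[str, RtcaTable]:
    """Read every sheet of an XLSX export into a dict of tables."""
    sheets = pd.read_excel(Path(path), sheet_name=None)
    return {
        name: _frame_to_table(df, f"{Path(path).name}[{name}]")
        for name, df in sheets.items()
    }


def write_rtca_table(table: RtcaTable, path: str | Path) -> None:
    """Write a table as CSV (columns time_h, ci_mean[, ci_sd])."""
    cols = {"time_h": table.times, "ci_mean": table.ci_mean}
    if table.ci_sd is not None:
        cols["ci_sd"] = table.ci_sd
    pd.DataFrame(cols).to_csv(path, index=False)


def write_rtca_workbook(tables: dict[str, RtcaTable], path: str | Path) -> None:
    """Write tables to an XLSX workbook, one sheet per table."""
    with pd.ExcelWriter(Path(path)) as xl:
        for name, table in tables.items():
            cols = {"time_h": table.times, "ci_mean": table.ci_mean}
            if table.ci_sd is not None:
                cols["ci_sd"] = table.ci_sd
            pd.DataFrame(cols).to_excel(xl, sheet_name=name[:31], index=False)


def average_replicates(tables: Sequence[RtcaTable]) -> Curve:
    """Average independent experiments into one reference curve.

    Tables are linearly interpolated onto the first table's time grid
    restricted to the common overlap; the returned SD is the sample SD
    of the per-experiment means at each time point (None for a single
    table).
    """
    if not tables:
        raise ValueError("need at least one table")
    lo = max(t.times[0] for t in tables)
    hi = min(t.times[-1] for t in tables)
    if lo > hi:
        raise ValueError("tables have disjoint time ranges")
    base = tables[0].times
    grid = base[(base >= lo) & (base <= hi)]
    if grid.size == 0:
        raise ValueError("no grid points inside the common time range")
    stack = np.vstack([np.interp(grid, t.times, t.ci_mean) for t in tables])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(tables) > 1 else None
    label = tables[0].label + f" (n={len(tables)})" if tables[0].label else ""
    return Curve(grid, mean, sd=sd, label=label)


def synthesize_experiment(
    params: ModelParameters,
    geometry: AssayGeometry,
    ic: InitialConditions,
    settings: SimulationSettings,
    noise_sd: float = 0.05,
    n_replicates: int = 4,
    n_experiments: int = 3,
    seed: int = 0,
    ci_map: CellIndexMap | None = None,
    label: str = "synthetic",
) -> list[RtcaTable]:
    """Generate synthetic RTCA exports from a simulation.

    Emulates the instrument's export: the model is simulated once, the
    migrated-cell curve is mapped to Cell Index and sampled at the
    recording cadence (``settings.output_interval``), and each of
    ``n_experiments`` independent experiments is built as the mean +/-
    SD of ``n_replicates`` wells with independent additive Gaussian
    noise of standard deviation ``noise_sd`` per well and time point.

    Deterministic for a fixed seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates < 1 or n_experiments < 1:
        raise ValueError("need at least one replicate and one experiment")
    ci_map = ci_map or CellIndexMap(a=1e-4)
    result = simulate(params, geometry, ic, settings)
    ci = to_cell_index(migrated_cell_number(result), ci_map)
    rng = np.random.default_rng(seed)
    tables = []
    for e in range(n_experiments):
        wells = ci.values[None, :] + rng.normal(
            0.0, noise_sd, size=(n_replicates, ci.values.size)
        )
        mean = wells.mean(axis=0)
        sd = wells.std(axis=0, ddof=1) if n_replicates > 1 else np.zeros_like(mean)
        tables.append(
            RtcaTable(
                times=ci.times.copy(),
                ci_mean=mean,
                ci_sd=sd,
                label=f"{label}_exp{e + 1}",
                n_replicates=n_replicates,
            )
        )
    return tables
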