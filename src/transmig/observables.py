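"""Cell-Index observables and goodness-of-fit.

The impedance analyser reports a dimensionless Cell Index that depends
linearly on the number of cells covering the biosensor below the
membrane.  This module converts the simulated lower-chamber cell number
into Cell-Index curves and quantifies the agreement between two curves
with the relative mean-squared error

    MSE = sum_i (chat_i - c_i)^2 / sum_i c_i^2,

where the simulated curve ``chat`` is linearly interpolated onto the
time grid of the reference curve ``c``.  Being a ratio, the relative
MSE is invariant under a joint rescaling of both curves, which makes it
usable even when the absolute Cell-Index-per-cell slope is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .solver import SimulationResult

__all__ = [
    "Curve",
    "CellIndexMap",
    "migrated_cell_number",
    "to_cell_index",
    "relative_mse",
    "fit_proportional_map",
]


@dataclass
class Curve:
    """A time series: times in hours, values, optional per-point SD."""

    times: np.ndarray
    values: np.ndarray
    sd: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.times.shape:
                raise ValueError("sd must match times in length")
            if np.any(self.sd < 0):
                raise ValueError("sd must be >= 0")

    def __len__(self) -> int:
        return self.times.size

    def to_csv(self, path: str | Path) -> None:
        cols = {"time_h": self.times, "value": self.values}
        if self.sd is not None:
            cols["sd"] = self.sd
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label: str = "") -> "Curve":
        df = pd.read_csv(path)
        sd = df["sd"].to_numpy() if "sd" in df.columns else None
        return cls(df["time_h"].to_numpy(), df["value"].to_numpy(), sd=sd,
                   label=label or Path(path).stem)


@dataclass(frozen=True)
class CellIndexMap:
    """Affine map from cell number to Cell Index: CI = a*N + b."""

    a: float
    b: float = 0.0
    proportional: bool = True

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("slope a must be > 0")
        if self.proportional and self.b != 0.0:
            raise ValueError("proportional map requires b = 0")


def migrated_cell_number(result: SimulationResult) -> Curve:
    """Number of migrated cells N_B(t): the cell density integrated over
    the whole lower chamber (trapezoid, lower membrane trace included)."""
    return Curve(result.times, result.n_lower, label="n_migrated")


def to_cell_index(n_curve: Curve, ci_map: CellIndexMap) -> Curve:
    """Apply the linear cell-number -> Cell-Index map pointwise."""
    sd = None if n_curve.sd is None else ci_map.a * n_curve.sd
    return Curve(
        n_curve.times,
        ci_map.a * n_curve.values + ci_map.b,
        sd=sd,
        label=n_curve.label,
    )


def relative_mse(sim: Curve, exp: Curve) -> float:
    """Relative MSE of a simulated curve against a reference curve.

    The simulated curve is linearly interpolated onto the reference time
    grid; reference points outside the simulated time range are dropped
    (no extrapolation).
    """
    lo = max(sim.times[0], exp.times[0])
    hi = min(sim.times[-1], exp.times[-1])
    keep = (exp.times >= lo) & (exp.times <= hi)
    if not np.any(keep):
        raise ValueError("curves have no overlapping time range")
    t = exp.times[keep]
    c = exp.values[keep]
    denom = float(np.sum(c**2))
    if denom == 0.0:
        raise ValueError("reference curve is identically zero on the overlap")
    chat = np.interp(t, sim.times, sim.values)
    return float(np.sum((chat - c) ** 2) / denom)


def fit_proportional_map(n_curve: Curve, target: Curve) -> CellIndexMap:
    """Least-squares proportional Cell-Index map between a simulated
    cell-number curve and a target Cell-Index curve.

    Minimises ``sum_i (a*N(t_i) - c_i)^2`` over the target grid
    (restricted to the overlap), i.e. ``a = sum(c*N)/sum(N^2)``.
    """
    lo = max(n_curve.times[0], target.times[0])
    hi = min(n_curve.times[-1], target.times[-1])
    keep = (target.times >= lo) & (target.times <= hi)
    if not np.any(keep):
        raise ValueError("curves have no overlapping time range")
    t = target.times[keep]
    c = target.values[keep]
    N = np.interp(t, n_curve.times, n_curve.values)
    nn = float(np.sum(N**2))
    if nn == 0.0:
        raise ValueError("simulated curve is identically zero on the overlap")
    a = float(np.sum(c * N) / nn)
    if a <= 0:
        raise ValueError("fitted slope is nonpositive; curves are incompatible")
    return CellIndexMap(a=a, b=0.0, proportional=True)
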