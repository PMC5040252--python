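"""Local one-at-a-time sensitivity analysis.

For a scalar model output ``f`` (the Cell Index at the end of the 12 h
observation window) and a parameter with baseline value ``p0``, the
local sensitivity index for a perturbation ``eps = eps_fraction * p0``
is the ratio of relative variations

    S = | (f(p0 +/- eps) - f(p0)) / f(p0) | * (eps / p0)^(-1),

reported as a magnitude, while the signed percentage output variation is

    dfrel = (f(p0 +/- eps) - f(p0)) / f(p0) * 100.

By construction S = |dfrel| / (100 * eps_fraction) for every record —
for the default 5% perturbation, S = |dfrel(%)| / 5.

The output is computed with a proportional Cell-Index map, so S and
dfrel do not depend on the (instrument-specific) Cell-Index-per-cell
slope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .observables import CellIndexMap, migrated_cell_number, to_cell_index
from .parameters import (
    AssayGeometry,
    InitialConditions,
    ModelParameters,
    SimulationSettings,
)
from .solver import SimulationResult, simulate

__all__ = [
    "SensitivityRecord",
    "DEFAULT_PARAMETERS",
    "output_functional",
    "sensitivity_index",
    "sensitivity_table",
]

#: parameters analysed by default: the data-driven constants of the model
DEFAULT_PARAMETERS: tuple[str, ...] = (
    "D_u",
    "chi1",
    "chi2",
    "V_transp",
    "alpha2",
    "delta",
    "k_u1",
    "k_u2",
    "k_u3",
    "k_phi",
)


@dataclass(frozen=True)
class SensitivityRecord:
    """One parameter perturbation: signed dfrel (%) and magnitude S."""

    parameter: str
    direction: str            # "+eps" or "-eps"
    eps_fraction: float
    f0: float
    f_perturbed: float
    delta_f_rel: float        # percent, signed
    S: float                  # magnitude


def output_functional(
    result: SimulationResult,
    ci_map: CellIndexMap | None = None,
    time: float = 12.0,
) -> float:
    """Cell Index at the stated observation time (default 12 h)."""
    ci_map = ci_map or CellIndexMap(a=1.0)
    ci = to_cell_index(migrated_cell_number(result), ci_map)
    if time > ci.times[-1] + 1e-9:
        raise ValueError(
            f"simulation ends at {ci.times[-1]:g} h, before the requested {time:g} h"
        )
    return float(np.interp(time, ci.times, ci.values))


def sensitivity_index(
    f0: float, f_pert: float, p0: float, eps: float
) -> tuple[float, float]:
    """Return (S, delta_f_rel_percent) for one perturbation.

    ``S`` is the magnitude of the relative-variation ratio; the percent
    variation keeps its sign.
    """
    if f0 == 0:
        raise ValueError("baseline output f0 = 0: sensitivity undefined")
    if p0 == 0:
        raise ValueError("baseline parameter p0 = 0: relative perturbation undefined")
    if eps <= 0:
        raise ValueError("eps must be > 0")
    rel = (f_pert - f0) / f0
    return abs(rel) / (eps / p0), 100.0 * rel


def sensitivity_table(
    params: ModelParameters,
    geometry: AssayGeometry,
    ic: InitialConditions,
    settings: SimulationSettings,
    param_names: Sequence[str] | None = None,
    eps_fraction: float = 0.05,
    directions: Sequence[str] = ("+eps", "-eps"),
    baseline_result: SimulationResult | None = None,
) -> list[SensitivityRecord]:
    """One-at-a-time sensitivity of the 12 h Cell Index.

    The baseline is simulated once; each record perturbs exactly one
    parameter by ``+/- eps_fraction`` and re-simulates.  A pre-computed
    ``baseline_result`` (same params/geometry/ic/settings) can be passed
    to avoid repeating the baseline run.
    """
    if eps_fraction <= 0:
        raise ValueError("eps_fraction must be > 0")
    names = tuple(param_names) if param_names is not None else DEFAULT_PARAMETERS
    for name in names:
        if not hasattr(params, name):
            raise KeyError(f"unknown parameter {name!r}")
    for d in directions:
        if d not in ("+eps", "-eps"):
            raise ValueError(f"unknown direction {d!r}")

    if baseline_result is None:
        baseline_result = simulate(params, geometry, ic, settings)
    f0 = output_functional(baseline_result, time=settings.t_end)

    records: list[SensitivityRecord] = []
    for name in names:
        p0 = getattr(params, name)
        if p0 == 0:
            raise ValueError(
                f"parameter {name!r} is 0 in the baseline; relative "
                "perturbation undefined"
            )
        eps = eps_fraction * p0
        for direction in directions:
            signed = eps if direction == "+eps" else -eps
            pert = params.replace(**{name: p0 + signed})
            res = simulate(pert, geometry, ic, settings)
            f_pert = output_functional(res, time=settings.t_end)
            S, dfrel = sensitivity_index(f0, f_pert, p0, eps)
            records.append(
                SensitivityRecord(
                    parameter=name,
                    direction=direction,
                    eps_fraction=eps_fraction,
                    f0=f0,
                    f_perturbed=f_pert,
                    delta_f_rel=dfrel,
                    S=S,
                )
            )
    return records
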