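"""Staged parameter calibration from proliferation and migration curves.

Calibration follows the staged protocol of the assay:

1. *proliferation* — the growth constants (rate ``alpha1`` and carrying
   capacity) are obtained by fitting a logistic trajectory to a
   proliferation Cell-Index curve recorded at serum level ``phi_bar``,
   where the model's serum factor equals one and the fitted rate is
   ``alpha1`` directly.
2. *basal* — the parameters with no chemotactic or growth role
   (``D_u``, ``V_transp``, ``k_u1``, ``k_u2``, ``k_u3``) are fitted to
   basal-migration curves with ``chi1 = alpha1 = 0``.
3. *migration* — the remaining constants (``chi1``, ``chi2``,
   ``alpha2``, ``delta``, ``k_phi``) are fitted to the full-migration
   curves with all earlier-stage parameters frozen.

The objective at stages 2-3 is the relative MSE between the simulated
Cell-Index curve and the target curve, with the (unknown) proportional
Cell-Index slope profiled out by least squares at every evaluation.
The search is a bounded Nelder-Mead simplex in log-parameter space with
a fixed-seed multi-start, which is robust for low-dimensional, noisy,
simulation-based objectives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit, minimize

from .observables import (
    CellIndexMap,
    Curve,
    fit_proportional_map,
    migrated_cell_number,
    relative_mse,
    to_cell_index,
)
from .parameters import (
    AssayGeometry,
    InitialConditions,
    ModelParameters,
    SimulationSettings,
    make_basal_parameters,
)
from .solver import simulate

__all__ = [
    "LogisticFit",
    "CalibrationProblem",
    "CalibrationResult",
    "STAGE_PARAMETERS",
    "fit_logistic_proliferation",
    "estimate_doubling_time",
    "calibrate",
]

log = logging.getLogger(__name__)

#: parameters each calibration stage is allowed to free
STAGE_PARAMETERS: dict[str, frozenset[str]] = {
    "basal": frozenset({"D_u", "V_transp", "k_u1", "k_u2", "k_u3"}),
    "migration": frozenset({"chi1", "chi2", "alpha2", "delta", "k_phi"}),
}


# ---------------------------------------------------------------------------
# proliferation stage


@dataclass(frozen=True)
class LogisticFit:
    """Result of fitting a logistic trajectory to a proliferation curve."""

    alpha1: float             # growth rate, h^-1
    capacity_ci: float        # carrying capacity in Cell-Index units
    c0: float                 # fitted initial Cell Index
    ci_map: Optional[CellIndexMap]  # CI per cell, when n_seeded is known
    alpha3: Optional[float]   # capacity in cell-number units, when mapped
    residual: float           # root-mean-square residual of the fit


def _logistic(t: np.ndarray, r: float, K: float, c0: float) -> np.ndarray:
    return K / (1.0 + (K / c0 - 1.0) * np.exp(-r * t))


def fit_logistic_proliferation(
    curve: Curve,
    phi_bar: float | None = None,
    n_seeded: float | None = None,
) -> LogisticFit:
    """Fit a logistic growth trajectory to a proliferation Cell-Index curve.

    Because proliferation assays are run at serum level ``phi_bar``, the
    model's serum factor equals one and the fitted rate is ``alpha1``
    directly (``phi_bar`` is accepted for the caller's bookkeeping; it
    does not enter the fit).  When the seeded cell number is given, the
    proportional Cell-Index map ``a = c0 / n_seeded`` is returned along
    with the capacity expressed in cell-number units (``alpha3``).
    """
    t = curve.times
    c = curve.values
    if np.any(c <= 0):
        raise ValueError("proliferation curve must be positive")
    if np.ptp(c) == 0.0:
        # degenerate plateau: zero growth at the observed level
        cap = float(c[0])
        ci_map = CellIndexMap(a=cap / n_seeded) if n_seeded else None
        return LogisticFit(0.0, cap, cap, ci_map,
                           n_seeded if n_seeded else None, 0.0)
    K0 = float(c.max()) * 1.05
    c00 = float(c[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.log(np.clip(c / c00, 1e-12, None))
    r0 = max(float(np.polyfit(t, y, 1)[0]), 1e-3)
    try:
        popt, _ = curve_fit(
            _logistic,
            t,
            c,
            p0=(r0, K0, c00),
            bounds=([0.0, c00 * 0.5, 1e-12], [10.0, 100.0 * K0, K0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise ValueError(f"logistic fit failed to converge: {exc}") from exc
    r, K, c0 = map(float, popt)
    resid = float(np.sqrt(np.mean((_logistic(t, r, K, c0) - c) ** 2)))
    if resid > 0.5 * float(np.std(c)):
        raise ValueError(
            f"logistic fit is degenerate (rms residual {resid:.3g} vs curve "
            f"spread {np.std(c):.3g}); curve may not be logistic"
        )
    ci_map = CellIndexMap(a=c0 / n_seeded) if n_seeded else None
    alpha3 = K / ci_map.a if ci_map else None
    return LogisticFit(r, K, c0, ci_map, alpha3, resid)


def estimate_doubling_time(
    curve: Curve, window: tuple[float, float] | None = None
) -> float:
    """Doubling time (h) from a log-linear fit on an exponential window."""
    t, c = curve.times, curve.values
    if window is not None:
        keep = (t >= window[0]) & (t <= window[1])
        t, c = t[keep], c[keep]
    if t.size < 2:
        raise ValueError("window contains fewer than two points")
    if np.any(c <= 0):
        raise ValueError("curve must be positive on the window")
    slope = float(np.polyfit(t, np.log(c), 1)[0])
    if slope <= 0:
        raise ValueError(f"nonpositive growth rate ({slope:.3g}/h) on the window")
    return float(np.log(2.0) / slope)


# ---------------------------------------------------------------------------
# simulation-based stages


@dataclass
class CalibrationProblem:
    """A bounded fit of selected model parameters to a target curve."""

    stage: str                                 # "basal" | "migration"
    free: Mapping[str, tuple[float, float]]    # name -> (lower, upper) bounds
    params: ModelParameters                    # fixed values / starting point
    geometry: AssayGeometry
    ic: InitialConditions
    settings: SimulationSettings
    target: Curve
    ci_map: Optional[CellIndexMap] = None
    max_evaluations: int = 400
    xtol: float = 1e-3
    n_starts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage not in STAGE_PARAMETERS:
            raise ValueError(
                f"stage must be one of {sorted(STAGE_PARAMETERS)}; proliferation "
                "curves are fitted with fit_logistic_proliferation"
            )
        allowed = STAGE_PARAMETERS[self.stage]
        bad = set(self.free) - allowed
        if bad:
            raise ValueError(
                f"parameters {sorted(bad)} cannot be freed at stage "
                f"{self.stage!r}; allowed: {sorted(allowed)}"
            )
        for name, (lo, hi) in self.free.items():
            if not 0 < lo < hi:
                raise ValueError(f"bounds for {name!r} must satisfy 0 < lo < hi")


@dataclass
class CalibrationResult:
    """Best parameter point found and its diagnostics."""

    params: ModelParameters
    values: dict[str, float]
    objective: float
    objective_at_start: float
    n_evaluations: int
    success: bool
    flat_parameters: list[str] = field(default_factory=list)
    message: str = ""


def _stage_settings(problem: CalibrationProblem) -> SimulationSettings:
    mode = "basal" if problem.stage == "basal" else "migration"
    s = problem.settings
    return SimulationSettings(
        dt=s.dt, t_end=s.t_end, mode=mode, output_interval=s.output_interval
    )


def calibrate(
    problem: CalibrationProblem,
    forward: Callable[..., object] = simulate,
) -> CalibrationResult:
    """Minimise the relative MSE over the free parameters.

    The free parameters are searched in log space within their bounds
    (all calibrated constants are positive scale parameters) with
    ``n_starts`` Nelder-Mead restarts from deterministic pseudo-random
    interior points.  Near-flat directions — free parameters whose
    +/-20% perturbation at the optimum changes the objective by less
    than 1e-4 — are reported in ``flat_parameters`` rather than trusted
    silently.
    """
    settings = _stage_settings(problem)
    names = list(problem.free)
    base = problem.params
    if problem.stage == "basal":
        base = make_basal_parameters(base)
    n_eval = 0

    def run_mse(p: ModelParameters) -> float:
        nonlocal n_eval
        n_eval += 1
        res = forward(p, problem.geometry, problem.ic, settings)
        n_curve = migrated_cell_number(res)
        ci_map = problem.ci_map
        if ci_map is None:
            # profile the unknown Cell-Index slope out by least squares
            try:
                ci_map = fit_proportional_map(n_curve, problem.target)
            except ValueError:
                return np.inf
        return relative_mse(to_cell_index(n_curve, ci_map), problem.target)

    def with_values(values: Sequence[float]) -> ModelParameters:
        return base.replace(**dict(zip(names, values)))

    start_values = [getattr(base, n) for n in names]
    f_start = run_mse(with_values(start_values) if names else base)

    if not names:
        return CalibrationResult(
            params=base,
            values={},
            objective=f_start,
            objective_at_start=f_start,
            n_evaluations=n_eval,
            success=bool(np.isfinite(f_start)),
            message="no free parameters; objective evaluated at the fixed point",
        )

    lb = np.log10([problem.free[n][0] for n in names])
    ub = np.log10([problem.free[n][1] for n in names])

    def objective(z: np.ndarray) -> float:
        val = run_mse(with_values(10.0 ** np.clip(z, lb, ub)))
        return val if np.isfinite(val) else 1e6

    rng = np.random.default_rng(problem.seed)
    starts = [np.clip(np.log10(start_values), lb, ub)]
    starts += [lb + (ub - lb) * rng.random(len(names))
               for _ in range(problem.n_starts - 1)]

    best_z, best_f = starts[0], np.inf
    budget = max(problem.max_evaluations // max(len(starts), 1), 20)
    for z0 in starts:
        opt = minimize(
            objective,
            z0,
            method="Nelder-Mead",
            options={
                "maxfev": budget,
                "xatol": problem.xtol,
                "fatol": 1e-10,
                "initial_simplex": None,
            },
        )
        if opt.fun < best_f:
            best_f, best_z = float(opt.fun), np.clip(opt.x, lb, ub)
    if not np.isfinite(best_f) or best_f >= 1e6:
        return CalibrationResult(
            params=base,
            values=dict(zip(names, start_values)),
            objective=f_start,
            objective_at_start=f_start,
            n_evaluations=n_eval,
            success=False,
            message="objective non-finite at every start",
        )
    # keep the starting point if the search did not improve on it
    if f_start <= best_f:
        best_f, best_z = f_start, np.clip(np.log10(start_values), lb, ub)

    best_values = dict(zip(names, 10.0**best_z))
    best_params = with_values(list(best_values.values()))

    flat = []
    for name in names:
        v = best_values[name]
        dmse = max(
            abs(run_mse(best_params.replace(**{name: v * 1.2})) - best_f),
            abs(run_mse(best_params.replace(**{name: v * 0.8})) - best_f),
        )
        if dmse < 1e-4:
            flat.append(name)
    if flat:
        log.warning(
            "near-flat calibration directions (|dMSE| < 1e-4 at +/-20%%): %s",
            ", ".join(flat),
        )

    return CalibrationResult(
        params=best_params,
        values=best_values,
        objective=best_f,
        objective_at_start=f_start,
        n_evaluations=n_eval,
        success=True,
        flat_parameters=flat,
    )
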