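"""Model parameters, assay geometry and constitutive functions.

The model describes a single well of an impedance-based transwell
(CIM-plate) migration assay as two stacked 1D chambers separated by a
porous membrane.  Two fields evolve in time: the cell line density
``u(x, t)`` (cell cm^-1) and the chemoattractant (FBS) density
``phi(x, t)`` (ul cm^-1).  Cells diffuse, drift spontaneously through
the membrane pores (basal migration), chemotax up the FBS gradient with
a saturating sensitivity, and increase their impedance footprint through
a logistic adhesion/spreading term that is switched on below the
membrane.  The membrane itself is a Kedem-Katchalsky interface: the flux
through it is proportional to the concentration jump across it, with a
crowding-dependent transmission coefficient for the cells.

This module holds the parameter containers, the Table-of-constants
presets for the three tumour cell lines studied with this assay
(chondrosarcoma Sarc, fibrosarcoma HT1080, melanoma A375), and the
scalar constitutive functions of the model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "ModelParameters",
    "AssayGeometry",
    "InitialConditions",
    "SimulationSettings",
    "chemotactic_sensitivity",
    "spreading_weight",
    "adhesion_spreading_rate",
    "membrane_transmission",
    "make_basal_parameters",
    "load_preset",
    "load_parameters",
    "dump_parameters",
    "PRESETS",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent parameter/geometry configuration."""


@dataclass(frozen=True)
class ModelParameters:
    """Constitutive constants of the migration-assay model.

    Units follow the 1D (per unit length) formulation of the model:
    densities are per cm of well height.

    Attributes
    ----------
    D_u : float
        Cell diffusion coefficient, cm^2 h^-1.
    D_phi : float
        Chemoattractant (FBS) diffusion coefficient, cm^2 h^-1.
    chi1 : float
        Maximal chemotactic sensitivity, cm^3 ul^-1 h^-1.
    chi2 : float
        FBS half-saturation of the chemotactic sensitivity, ul cm^-1.
    V_transp : float
        Spontaneous transport speed through the membrane pores,
        cm h^-1, directed top -> bottom (positive x).
    alpha1 : float
        Logistic adhesion/spreading (growth) coefficient, h^-1.
    alpha2 : float
        FBS half-saturation in the growth term, ul cm^-1.
    alpha3 : float
        Logistic carrying capacity, cell cm^-1.
    phi_bar : float
        FBS concentration of the proliferation experiment used to
        calibrate the growth term, ul cm^-1.
    delta : float
        FBS binding/consumption rate by cells, cm h^-1 cell^-1.
    k_u1 : float
        Membrane transmission coefficient for cells, cm h^-1.
    k_u2 : float
        Upper-side crowding coefficient, cm cell^-1.
    k_u3 : float
        Lower-side crowding coefficient, cell^-2.
    k_phi : float
        Membrane transmission coefficient for FBS, cm h^-1.
    p_crowd : float
        Exponent on the lower-chamber cell number in the crowding
        denominator; 2 by default.
    x_bar_offset : float
        Distance above the membrane at which the spreading weight W
        vanishes, cm; on the order of two cell diameters.
    """

    D_u: float
    D_phi: float
    chi1: float
    chi2: float
    V_transp: float
    alpha1: float
    alpha2: float
    alpha3: float
    phi_bar: float
    delta: float
    k_u1: float
    k_u2: float
    k_u3: float
    k_phi: float
    p_crowd: float = 2.0
    x_bar_offset: float = 4e-3

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ConfigurationError(f"{f.name} must be finite, got {v!r}")
            if v < 0:
                raise ConfigurationError(f"{f.name} must be >= 0, got {v!r}")
        if self.alpha3 <= 0:
            raise ConfigurationError("alpha3 must be > 0")
        if self.chi2 <= 0:
            raise ConfigurationError("chi2 must be > 0")
        if self.alpha1 > 0 and self.phi_bar <= 0:
            raise ConfigurationError("phi_bar must be > 0 when alpha1 > 0")

    def replace(self, **changes: float) -> "ModelParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class AssayGeometry:
    """1D geometry of one transwell, x-axis oriented top -> bottom.

    The well is the interval ``[x_top, x_bottom]`` with the porous
    membrane at ``x_M``.  The normal used in every flux condition is the
    downward versor, so positive fluxes and velocities point from the
    upper into the lower chamber.  The mesh is coarse (``dx_coarse``)
    away from the membrane and refined to ``dx_fine`` inside
    ``[x_M - fine_halfwidth, x_M + fine_halfwidth]``.
    """

    x_top: float = 0.0
    x_bottom: float = 1.8
    x_M: float = 0.9
    dx_coarse: float = 1e-2
    dx_fine: float = 1e-6
    fine_halfwidth: float | None = None

    def __post_init__(self) -> None:
        if not self.x_top < self.x_M < self.x_bottom:
            raise ConfigurationError("require x_top < x_M < x_bottom")
        if not 0 < self.dx_fine <= self.dx_coarse:
            raise ConfigurationError("require 0 < dx_fine <= dx_coarse")
        hw = self.halfwidth
        if hw <= 0:
            raise ConfigurationError("fine_halfwidth must be > 0")
        if self.x_M - hw <= self.x_top or self.x_M + hw >= self.x_bottom:
            raise ConfigurationError("refined zone must lie strictly inside the well")

    @property
    def halfwidth(self) -> float:
        return self.dx_coarse if self.fine_halfwidth is None else self.fine_halfwidth

    @property
    def upper_length(self) -> float:
        return self.x_M - self.x_top

    @property
    def lower_length(self) -> float:
        return self.x_bottom - self.x_M


@dataclass(frozen=True)
class InitialConditions:
    """Initial fields: a cell slab in the upper chamber, FBS below.

    ``u = u0`` on the sub-interval ``omega_u`` of the upper chamber and
    zero elsewhere; ``phi = phi0`` on the whole lower chamber and zero
    above (phi0 = 0 reproduces the basal, serum-free configuration).
    """

    u0: float
    phi0: float
    n_total: float
    omega_u: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.omega_u
        if not lo < hi:
            raise ConfigurationError("omega_u must be a nonempty interval")
        if self.u0 < 0 or self.phi0 < 0 or self.n_total < 0:
            raise ConfigurationError("u0, phi0, n_total must be >= 0")
        if self.n_total > 0:
            mass = self.u0 * (hi - lo)
            if abs(mass - self.n_total) > 1e-3 * self.n_total:
                raise ConfigurationError(
                    f"u0*|omega_u| = {mass:.6g} differs from n_total = "
                    f"{self.n_total:.6g} by more than 0.1%"
                )

    @classmethod
    def seeded(
        cls,
        n_total: float,
        u0: float,
        geometry: AssayGeometry,
        phi0: float = 0.0,
    ) -> "InitialConditions":
        """Place ``n_total`` cells at density ``u0`` against the membrane.

        The slab of length ``n_total / u0`` sits immediately above the
        membrane (cells sediment onto it after seeding).
        """
        length = n_total / u0
        lo = geometry.x_M - length
        if lo <= geometry.x_top:
            raise ConfigurationError("seeded slab does not fit in the upper chamber")
        return cls(u0=u0, phi0=phi0, n_total=n_total, omega_u=(lo, geometry.x_M))


@dataclass(frozen=True)
class SimulationSettings:
    """Time discretisation and output cadence."""

    dt: float = 1e-3
    t_end: float = 12.0
    mode: str = "migration"
    output_interval: float = 0.25
    store_snapshots: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_end <= 0:
            raise ConfigurationError("dt and t_end must be > 0")
        if self.output_interval < self.dt:
            raise ConfigurationError("output_interval must be >= dt")
        if self.mode not in ("basal", "migration"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")


# ---------------------------------------------------------------------------
# constitutive functions

ArrayLike = Union[float, np.ndarray]


def chemotactic_sensitivity(phi: ArrayLike, params: ModelParameters) -> ArrayLike:
    """Saturating chemotactic sensitivity chi(phi) = chi1*phi/(chi2+phi).

    Monotone nondecreasing in phi, bounded by chi1; the half-saturation
    point is phi = chi2.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0):
        raise ValueError("phi must be >= 0")
    out = params.chi1 * phi / (params.chi2 + phi)
    return out if out.ndim else float(out)


def spreading_weight(
    x: ArrayLike, geometry: AssayGeometry, params: ModelParameters
) -> ArrayLike:
    """Spatial weight W(x) confining adhesion/spreading to the membrane zone.

    W = 0 above x_bar = x_M - x_bar_offset, W = 1 below the membrane, and
    a smooth (C-infinity) bump-function ramp in between::

        W(x) = exp(-(x_bar - x_M)^2 / ((x_bar - x_M)^2 - (x - x_M)^2) + 1)

    for x_bar < x <= x_M.  Continuous and nondecreasing on the well.
    """
    if params.x_bar_offset <= 0:
        raise ConfigurationError("x_bar_offset must be > 0")
    x = np.asarray(x, dtype=float)
    x_M = geometry.x_M
    x_bar = x_M - params.x_bar_offset
    d2 = (x_bar - x_M) ** 2
    out = np.zeros_like(x)
    out[x > x_M] = 1.0
    ramp = (x > x_bar) & (x <= x_M)
    if np.any(ramp):
        denom = d2 - (x[ramp] - x_M) ** 2
        with np.errstate(divide="ignore", over="ignore"):
            expo = -d2 / denom + 1.0
            out[ramp] = np.exp(np.minimum(expo, 0.0))
    return out if out.ndim else float(out)


def adhesion_spreading_rate(
    u: ArrayLike,
    phi: ArrayLike,
    x: ArrayLike,
    params: ModelParameters,
    geometry: AssayGeometry,
) -> ArrayLike:
    """Logistic adhesion/spreading source g(u, phi, x), cell cm^-1 h^-1.

    ``g = alpha1 * u * (1 - u/alpha3) * [phi/(alpha2+phi)] *
    [(alpha2+phi_bar)/phi_bar] * W(x)``.  The FBS factor is normalised so
    that at the proliferation-assay serum level ``phi = phi_bar`` the
    rate reduces to plain logistic growth at rate alpha1.
    """
    if params.alpha1 > 0 and params.phi_bar <= 0:
        raise ConfigurationError("phi_bar must be > 0 when alpha1 > 0")
    u = np.asarray(u, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(u < 0) or np.any(phi < 0):
        raise ValueError("u and phi must be >= 0")
    if params.alpha1 == 0:
        out = np.zeros(np.broadcast(u, phi, np.asarray(x)).shape)
        return out if out.ndim else 0.0
    fbs = phi / (params.alpha2 + phi) * (params.alpha2 + params.phi_bar) / params.phi_bar
    W = spreading_weight(x, geometry, params)
    out = params.alpha1 * u * (1.0 - u / params.alpha3) * fbs * W
    return out if np.ndim(out) else float(out)


def membrane_transmission(
    u_T: float, n_lower: float, params: ModelParameters
) -> float:
    """Crowding-limited cell transmission coefficient of the membrane.

    ``k_u = k_u1 / (1 + k_u2*u_T + k_u3*n_lower**p)`` where ``u_T`` is
    the cell density on the upper face and ``n_lower`` the cell number
    already in the lower chamber.  Bounded by k_u1, strictly decreasing
    in both arguments.
    """
    if u_T < 0 or n_lower < 0:
        raise ValueError("u_T and n_lower must be >= 0")
    denom = 1.0 + params.k_u2 * u_T + params.k_u3 * n_lower**params.p_crowd
    return params.k_u1 / denom


def make_basal_parameters(params: ModelParameters) -> ModelParameters:
    """Parameter set of the basal (serum-free) migration experiment.

    Setting chi1 = alpha1 = 0 removes chemotaxis and adhesion/spreading,
    decoupling the cell equation from the FBS equation; only spontaneous
    transport, diffusion and membrane transmission remain.
    """
    return params.replace(chi1=0.0, alpha1=0.0)


# ---------------------------------------------------------------------------
# presets

#: Calibrated constants per cell line (migration condition, 2e4 cells/well),
#: plus the seeding densities u0 (cell cm^-1, keyed by cells/well) and the
#: initial/reference FBS levels shared by all lines.
PRESETS: dict[str, dict] = {
    "sarc": {
        "params": dict(
            D_u=1e-3, D_phi=3.7e-3, chi1=3e-3, chi2=4.75e-8, V_transp=9e-3,
            alpha1=0.154, alpha2=1e-6, alpha3=2.08e5, phi_bar=19.64,
            delta=1e-8, k_u1=2.0, k_u2=1e-5, k_u3=6e-8, k_phi=8.8e-2,
        ),
        "u0": {20000: 30200.0, 30000: 45300.0, 40000: 60400.0},
        "phi0": 18.39,
    },
    "ht1080": {
        "params": dict(
            D_u=2.5e-3, D_phi=3.7e-3, chi1=2.5e-3, chi2=4.75e-8, V_transp=2e-3,
            alpha1=0.135, alpha2=1e-6, alpha3=2.26e5, phi_bar=19.64,
            delta=1e-8, k_u1=2.0, k_u2=5e-5, k_u3=6e-8, k_phi=8.8e-2,
        ),
        "u0": {20000: 30200.0},
        "phi0": 18.39,
    },
    "a375": {
        "params": dict(
            D_u=8e-4, D_phi=3.7e-3, chi1=1e-3, chi2=4.75e-8, V_transp=1.3e-9,
            alpha1=0.118, alpha2=1e-6, alpha3=1.04e5, phi_bar=19.64,
            delta=3.5e-5, k_u1=2.0, k_u2=2e-8, k_u3=6e-8, k_phi=8.8e-2,
        ),
        "u0": {20000: 30200.0},
        "phi0": 18.39,
    },
}


def load_preset(
    name: str,
    n_cells: int = 20000,
    mode: str = "migration",
    geometry: AssayGeometry | None = None,
) -> tuple[ModelParameters, AssayGeometry, InitialConditions]:
    """Return (parameters, geometry, initial conditions) for a cell line.

    Parameters
    ----------
    name : {"sarc", "ht1080", "a375"}
        Cell line.
    n_cells : int
        Seeded cells per well; must be one of the seeding densities the
        preset defines.
    mode : {"migration", "basal"}
        Basal mode zeroes chi1/alpha1 and starts with no FBS.
    """
    key = name.lower()
    if key not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        )
    entry = PRESETS[key]
    if n_cells not in entry["u0"]:
        raise KeyError(
            f"preset {name!r} has no u0 for {n_cells} cells/well; "
            f"available: {sorted(entry['u0'])}"
        )
    params = ModelParameters(**entry["params"])
    geometry = geometry or AssayGeometry()
    phi0 = entry["phi0"]
    if mode == "basal":
        params = make_basal_parameters(params)
        phi0 = 0.0
    elif mode != "migration":
        raise ConfigurationError(f"unknown mode {mode!r}")
    ic = InitialConditions.seeded(
        n_total=float(n_cells), u0=entry["u0"][n_cells], geometry=geometry, phi0=phi0
    )
    return params, geometry, ic


def load_parameters(path: str | Path) -> ModelParameters:
    """Read a ModelParameters JSON file (symbol-named keys, SI-h units)."""
    data = json.loads(Path(path).read_text())
    data.pop("_units", None)
    data.pop("_comment", None)
    return ModelParameters(**data)


def dump_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write a ModelParameters JSON file."""
    data = {f.name: getattr(params, f.name) for f in fields(params)}
    Path(path).write_text(json.dumps(data, indent=2) + "\n")
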