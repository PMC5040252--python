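"""Non-uniform 1D mesh with a duplicated membrane node.

The membrane is an internal interface across which the fields are
discontinuous (the Kedem-Katchalsky conditions relate one-sided traces,
not a single nodal value).  The mesh therefore stores *two* nodes at the
membrane coordinate: ``i_T`` carries the upper-chamber trace, ``i_B``
(= i_T + 1) the lower-chamber trace.  Away from the membrane the mesh is
coarse; inside ``[x_M - halfwidth, x_M + halfwidth]`` it is refined, as
needed to keep the solution non-negative near the interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .parameters import AssayGeometry

__all__ = ["Mesh", "build_mesh"]


@dataclass(frozen=True)
class Mesh:
    """Node coordinates ordered top -> bottom, membrane node duplicated.

    ``x[i_T] == x[i_B] == x_M``.  Upper-chamber nodes are ``0..i_T``,
    lower-chamber nodes ``i_B..n-1``; coordinates are strictly
    increasing within each chamber.
    """

    x: np.ndarray
    i_T: int
    geometry: AssayGeometry

    @property
    def i_B(self) -> int:
        return self.i_T + 1

    @property
    def n_nodes(self) -> int:
        return self.x.size

    @property
    def x_upper(self) -> np.ndarray:
        return self.x[: self.i_T + 1]

    @property
    def x_lower(self) -> np.ndarray:
        return self.x[self.i_B :]

    @property
    def h_membrane_upper(self) -> float:
        """Spacing of the two nodes just above the membrane."""
        return self.x[self.i_T] - self.x[self.i_T - 1]

    @property
    def h_membrane_lower(self) -> float:
        return self.x[self.i_B + 1] - self.x[self.i_B]

    def integrate(self, values: np.ndarray) -> float:
        """Composite trapezoid of a nodal field over the whole well."""
        return self.integrate_upper(values) + self.integrate_lower(values)

    def integrate_upper(self, values: np.ndarray) -> float:
        return float(np.trapezoid(values[: self.i_T + 1], self.x_upper))

    def integrate_lower(self, values: np.ndarray) -> float:
        return float(np.trapezoid(values[self.i_B :], self.x_lower))


def _graded_segment(lo: float, hi: float, dx: float) -> np.ndarray:
    n = max(1, round((hi - lo) / dx))
    return np.linspace(lo, hi, n + 1)


def build_mesh(geometry: AssayGeometry) -> Mesh:
    """Build the composite coarse/fine mesh for a given geometry.

    The refined zone ``[x_M - hw, x_M + hw]`` is snapped to the nearest
    coarse nodes (with a warning) if its edges do not fall on the coarse
    lattice anchored at the well lids.
    """
    g = geometry
    hw = g.halfwidth
    lo_target, hi_target = g.x_M - hw, g.x_M + hw

    # snap zone edges onto the coarse lattices anchored at x_top / x_bottom
    lo = g.x_top + round((lo_target - g.x_top) / g.dx_coarse) * g.dx_coarse
    hi = g.x_bottom - round((g.x_bottom - hi_target) / g.dx_coarse) * g.dx_coarse
    if abs(lo - lo_target) > 1e-12 * g.dx_coarse or abs(hi - hi_target) > 1e-12 * g.dx_coarse:
        warnings.warn(
            "refined zone edges adjusted to the nearest coarse nodes: "
            f"[{lo_target:g}, {hi_target:g}] -> [{lo:g}, {hi:g}]",
            stacklevel=2,
        )
    if not g.x_top < lo < g.x_M < hi < g.x_bottom:
        raise ValueError("refined zone collapsed; decrease fine_halfwidth")

    upper_coarse = _graded_segment(g.x_top, lo, g.dx_coarse)
    fine_above = _graded_segment(lo, g.x_M, g.dx_fine)
    fine_below = _graded_segment(g.x_M, hi, g.dx_fine)
    lower_coarse = _graded_segment(hi, g.x_bottom, g.dx_coarse)

    upper = np.concatenate([upper_coarse[:-1], fine_above])
    lower = np.concatenate([fine_below[:-1], lower_coarse])
    # duplicate the membrane node: upper ends at x_M, lower starts at x_M
    x = np.concatenate([upper, [g.x_M], lower[1:]])
    x[upper.size] = g.x_M  # exact duplicate coordinate
    i_T = upper.size - 1
    assert x[i_T] == x[i_T + 1] == g.x_M
    return Mesh(x=x, i_T=i_T, geometry=g)
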