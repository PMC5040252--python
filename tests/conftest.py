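"""Shared fixtures.

Expensive default-mesh simulations (the production mesh: dx = 1e-2 cm,
dx_f = 1e-6 cm, dt = 1e-3 h) are session-scoped so the acceptance-level
checks share one baseline run.  Everything else runs on a coarse
validation mesh (uniform dx = 0.05 cm, dt = 1e-2 h) that reproduces the
same physics in a fraction of a second.
"""

from __future__ import annotations

import pytest
from hypothesis import settings as hsettings

from transmig import (
    AssayGeometry,
    SimulationSettings,
    load_preset,
    simulate,
)

hsettings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
hsettings.load_profile("ci")


@pytest.fixture(scope="session")
def coarse_geometry() -> AssayGeometry:
    return AssayGeometry(dx_coarse=0.05, dx_fine=0.05)


@pytest.fixture(scope="session")
def sarc_migration():
    """Sarc migration preset (params, geometry, ic) at the default geometry."""
    return load_preset("sarc", mode="migration")


@pytest.fixture(scope="session")
def sarc_basal_coarse(coarse_geometry):
    return load_preset("sarc", mode="basal", geometry=coarse_geometry)


@pytest.fixture(scope="session")
def sarc_migration_coarse(coarse_geometry):
    return load_preset("sarc", mode="migration", geometry=coarse_geometry)


@pytest.fixture(scope="session")
def default_migration_result(sarc_migration):
    """Full 12 h Sarc migration run at the production mesh and time step."""
    params, geometry, ic = sarc_migration
    return simulate(params, geometry, ic, SimulationSettings(dt=1e-3, t_end=12.0))


@pytest.fixture(scope="session")
def default_basal_result():
    """Full 12 h Sarc basal run at the production mesh and time step."""
    params, geometry, ic = load_preset("sarc", mode="basal")
    return simulate(
        params, geometry, ic, SimulationSettings(dt=1e-3, t_end=12.0, mode="basal")
    )


@pytest.fixture(scope="session")
def coarse_migration_result(sarc_migration_coarse):
    params, geometry, ic = sarc_migration_coarse
    return simulate(params, geometry, ic, SimulationSettings(dt=1e-2, t_end=12.0))
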