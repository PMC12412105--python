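"""Shared fixtures.

The expensive simulation runs (the Monte Carlo sorting sweep, the DPD fluid
bursts, the grafted-network swelling runs) are session-scoped so module tests
and acceptance tests assert against the same computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from thermosort import dpd_film as dpd
from thermosort import mc_cellsort as mc


@pytest.fixture(scope="session")
def mc_sweep_result():
    """Seed-averaged (D_d, B_p) sweep at the published working conditions."""
    params = mc.MCParams(seed=2024, desorption_steps=1_000_000, sample_every=250)
    grid = np.arange(0.225, 0.425 + 1e-9, 0.025)
    return mc.sweep(params, [0.5, 2.0], grid, n_seeds=3)


@pytest.fixture(scope="session")
def dpd_fluid_rho3():
    """Equilibrated pure DPD fluid at the standard density (thermostat checks)."""
    sys = dpd.make_fluid(box=(8.0, 8.0, 8.0), rho_b=3.0, seed=7)
    dpd.integrate(sys, 600)
    stats = dpd.integrate(sys, 1500, sample_every=10)
    return sys, stats


@pytest.fixture(scope="session")
def dpd_fluid_rho5():
    """Denser fluid, where the quadratic equation-of-state fit is accurate."""
    sys = dpd.make_fluid(box=(6.0, 6.0, 6.0), rho_b=5.0, seed=8)
    dpd.integrate(sys, 600)
    stats = dpd.integrate(sys, 1200, sample_every=10)
    return sys, stats


@pytest.fixture(scope="session")
def crosslink_run():
    """Dense active system cross-linked without a target cap: trace + system."""
    spec = dpd.NetworkSpec(
        n_beads=30, rho_g=0.4, gma_fraction=0.5, nu_cr_target=100.0,
        box=(7.0, 7.0, 15.0), seed=5,
    )
    sys = dpd.build_grafted_matrix(spec)
    dpd.integrate(sys, 500)
    stats = dpd.crosslink(sys, spec, 1200)
    return sys, stats


@pytest.fixture(scope="session")
def barometric_samples():
    """Height samples of non-adhesive cells under gravity only (closed form)."""
    params = mc.MCParams(seed=99, adsorption_steps=4_000_000, sample_every=4000)
    surface = mc.place_domains_rsa(240.0, 0.5, 0.0, seed=1)
    cells = mc.initialize_cells(surface, params, N1=50, N2=50, A_1d=0.0, A_2d=0.0)
    res = mc.run_adsorption(surface, cells, params, collect_z=20000)
    z_min = surface.H_d + cells.D / 2.0 - params.delta_max
    z_max = params.box_height - cells.D / 2.0
    return res.z_samples, z_min, z_max, params


@pytest.fixture(scope="session")
def swelling_band_run():
    """The grafted-network swelling experiment at the published condition."""
    spec = dpd.NetworkSpec(
        n_beads=100, rho_g=0.2, nu_cr_target=6.0, box=(8.0, 8.0, 36.0), seed=11
    )
    return dpd.swelling_experiment(spec)
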