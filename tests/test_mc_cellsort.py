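"""Monte Carlo cell-sorting model: geometry oracles, dynamics, and protocol."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats
from scipy.spatial import cKDTree

from thermosort import mc_cellsort as mc


@pytest.fixture(scope="module")
def surface_small():
    return mc.place_domains_rsa(120.0, 0.5, 0.48, seed=3)


@pytest.fixture(scope="module")
def surface_tree(surface_small):
    return cKDTree(surface_small.centers, boxsize=surface_small.L)


def covered_fraction(tree, surface, x, y, radius, n=100_000, seed=0):
    """Sampling oracle: fraction of a disc at (x, y) covered by domain tops."""
    rng = np.random.default_rng(seed)
    th = rng.uniform(0, 2 * np.pi, n)
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    px = (x + r * np.cos(th)) % surface.L
    py = (y + r * np.sin(th)) % surface.L
    d, _ = tree.query(np.column_stack([px, py]))
    return float(np.mean(d < surface.D_d / 2.0))


# --------------------------------------------------------------------------- #
# domain placement
# --------------------------------------------------------------------------- #


def test_rsa_count_formula():
    surf = mc.place_domains_rsa(240.0, 2.0, 0.48, seed=1)
    assert len(surf.centers) == round(0.48 * 240.0**2 / math.pi)  # 8801
    assert abs(surf.coverage - 0.48) <= 0.005


def test_rsa_no_overlaps_brute_force():
    surf = mc.place_domains_rsa(240.0, 2.0, 0.48, seed=2)
    tree = cKDTree(surf.centers, boxsize=surf.L)
    assert len(tree.query_pairs(surf.D_d - 1e-9)) == 0


def test_rsa_determinism_and_empty():
    a = mc.place_domains_rsa(60.0, 1.0, 0.3, seed=9)
    b = mc.place_domains_rsa(60.0, 1.0, 0.3, seed=9)
    assert np.array_equal(a.centers, b.centers)
    assert len(mc.place_domains_rsa(60.0, 1.0, 0.0, seed=0).centers) == 0


def test_rsa_rejects_jamming_coverage():
    with pytest.raises(ValueError):
        mc.place_domains_rsa(60.0, 1.0, 0.53, seed=0)


# --------------------------------------------------------------------------- #
# area operations vs sampling oracles
# --------------------------------------------------------------------------- #


def test_contact_area_oracle(surface_small, surface_tree):
    """Facet-domain lens sums agree with point sampling within 1%."""
    rng = np.random.default_rng(1)
    surf = surface_small
    for k in range(25):
        x, y = rng.uniform(0, surf.L, 2)
        u = rng.uniform(2.1, 4.9)
        a = math.sqrt(25.0 - u * u)
        got = mc.contact_area(np.array([x, y, surf.H_d + u]), surf, 10.0, 3.0)
        want = covered_fraction(surface_tree, surf, x, y, a, seed=k) * math.pi * a * a
        assert got == pytest.approx(want, rel=0.01, abs=0.05)


def test_repulsion_area_oracle(surface_small, surface_tree):
    surf = surface_small
    surf.swollen = True
    surf.h_p = 0.5
    rng = np.random.default_rng(2)
    for k in range(25):
        x, y = rng.uniform(0, surf.L, 2)
        u = rng.uniform(2.1, 5.2)
        d = u - surf.h_p
        b = 5.0 if d <= 0 else math.sqrt(max(25.0 - d * d, 0.0))
        got = mc.repulsion_area(np.array([x, y, surf.H_d + u]), surf, 10.0)
        want = (1.0 - covered_fraction(surface_tree, surf, x, y, b, seed=100 + k)) * math.pi * b * b
        assert got == pytest.approx(want, rel=0.01, abs=0.05)
    surf.swollen = False


def test_contact_tangent_and_containment(surface_small):
    surf = surface_small
    pos = np.array([10.0, 10.0, surf.H_d + 5.0])
    assert mc.contact_area(pos, surf, 10.0, 3.0) == 0.0  # just touching
    # facet fully inside one giant domain -> full facet area
    giant = mc.MicroSurface(L=100.0, D_d=40.0, sigma_d=0.0,
                            centers=np.array([[50.0, 50.0]]))
    u = 4.0
    a = math.sqrt(25.0 - u * u)
    got = mc.contact_area(np.array([50.0, 50.0, giant.H_d + u]), giant, 10.0, 3.0)
    assert got == pytest.approx(math.pi * a * a, rel=1e-9)


def test_repulsion_requires_swollen_state(surface_small):
    surface_small.swollen = False
    with pytest.raises(RuntimeError):
        mc.repulsion_area(np.array([1.0, 1.0, 10.0]), surface_small, 10.0)


def test_total_energy_term_assembly():
    """E = A_kd*contact + B_p*repulsion + g_w*z with each term checked."""
    surf = mc.MicroSurface(L=100.0, D_d=40.0, sigma_d=0.0,
                           centers=np.array([[50.0, 50.0]]),
                           swollen=True, h_p=0.5, B_p=0.32)
    cells = mc.CellEnsemble(
        positions=np.array([[50.0, 50.0, surf.H_d + 4.0]]),
        types=np.array([1]), A_1d=-0.4, A_2d=-0.3,
    )
    params = mc.MCParams(g_w=0.1, delta_max=3.0, h_p=0.5)
    z = surf.H_d + 4.0
    contact = mc.contact_area(cells.positions[0], surf, 10.0, 3.0)
    rep = mc.repulsion_area(cells.positions[0], surf, 10.0)
    expected = -0.4 * contact + 0.32 * rep + 0.1 * z
    got = mc.total_energy(cells.positions[0], 1, surf, cells, params)
    assert got == pytest.approx(expected, rel=1e-12)
    # suspended cell, collapsed polymer: gravity only
    surf2 = mc.MicroSurface(L=100.0, D_d=0.5, sigma_d=0.0, centers=np.empty((0, 2)))
    pos = np.array([10.0, 10.0, 30.0])
    assert mc.total_energy(pos, 2, surf2, cells, params) == pytest.approx(0.1 * 30.0)


def test_hard_wall_violation_raises(surface_small):
    params = mc.MCParams()
    cells = mc.CellEnsemble(positions=np.zeros((1, 3)), types=np.array([1]))
    low = np.array([5.0, 5.0, surface_small.H_d + 5.0 - params.delta_max - 0.1])
    with pytest.raises(ValueError):
        mc.total_energy(low, 1, surface_small, cells, params)


# --------------------------------------------------------------------------- #
# Metropolis dynamics
# --------------------------------------------------------------------------- #


def test_metropolis_acceptance_frequency():
    """At dE = 1, T = 1 the acceptance frequency is exp(-1) = 0.368 +- 0.01."""
    rng = np.random.default_rng(42)
    acc = sum(mc.accept_move(1.0, 1.0, rng) for _ in range(10_000))
    assert acc / 10_000 == pytest.approx(math.exp(-1.0), abs=0.01)
    assert mc.accept_move(-0.5, 1.0, rng)  # downhill always accepted


def test_mc_step_respects_hard_constraints(surface_small):
    params = mc.MCParams(seed=0, max_disp=1.0)
    cells = mc.initialize_cells(surface_small, params, N1=10, N2=10)
    rng = np.random.default_rng(5)
    for _ in range(300):
        mc.mc_step(surface_small, cells, params, rng)
    delta = cells.positions[:, None, :] - cells.positions[None, :, :]
    delta[:, :, :2] -= np.round(delta[:, :, :2] / surface_small.L) * surface_small.L
    d = np.sqrt((delta**2).sum(-1))
    np.fill_diagonal(d, np.inf)
    assert d.min() >= cells.D - 1e-9
    z_min = surface_small.H_d + cells.D / 2 - params.delta_max
    assert cells.positions[:, 2].min() >= z_min - 1e-9


def test_barometric_height_distribution(barometric_samples):
    """Gravity-only cells sample exp(-g z / T) (two-sample via exact CDF)."""
    z, z_min, z_max, params = barometric_samples
    assert len(z) >= 10_000
    z = z[::2][:10_000]
    lam = params.g_w / params.T_eff

    def cdf(x):
        return (1 - np.exp(-lam * (x - z_min))) / (1 - np.exp(-lam * (z_max - z_min)))

    res = stats.kstest(z, cdf)
    assert res.pvalue > 0.01


def test_stage_kernel_preserves_hard_constraints(surface_small):
    """Pairwise scan after each 10^4-step chunk finds no overlap."""
    params = mc.MCParams(seed=17, desorption_steps=10_000, adsorption_steps=20_000)
    cells = mc.initialize_cells(surface_small, params, N1=15, N2=15)
    mc.run_adsorption(surface_small, cells, params)
    for chunk in range(3):
        mc.run_desorption(surface_small, cells, replace(params, seed=chunk), 0.3)
        delta = cells.positions[:, None, :] - cells.positions[None, :, :]
        delta[:, :, :2] -= np.round(delta[:, :, :2] / surface_small.L) * surface_small.L
        d = np.sqrt((delta**2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= cells.D - 1e-9
    surface_small.swollen = False


# --------------------------------------------------------------------------- #
# protocol and observables
# --------------------------------------------------------------------------- #


def test_packing_fraction_identity():
    """N = 200 cells of diameter 10 on L = 240: printed density and packing."""
    N, D, L = 200, 10.0, 240.0
    assert N / L**2 == pytest.approx(3.472e-3, rel=1e-3)
    assert N * math.pi * (D / 2) ** 2 / L**2 == pytest.approx(0.273, abs=5e-4)


def test_adsorption_attaches_all_cells():
    """Collapsed polymer, B_p = 0: the stage ends with every cell attached."""
    params = mc.MCParams(seed=4, adsorption_steps=400_000)
    surf = mc.place_domains_rsa(120.0, 0.5, 0.48, seed=21)
    cells = mc.initialize_cells(surf, params, N1=25, N2=25)
    res = mc.run_adsorption(surf, cells, params)
    u = cells.positions[:, 2] - surf.H_d
    attached = np.mean(u <= params.r_cut(cells.D))
    assert attached == 1.0
    assert res.saturation_step is not None
    assert res.saturation_step < params.adsorption_steps


def test_desorption_limits(surface_small):
    """B_p = 0 with swollen geometry keeps ~all cells; huge B_p empties it."""
    params = mc.MCParams(seed=6, adsorption_steps=300_000, desorption_steps=300_000)
    cells = mc.initialize_cells(surface_small, params, N1=20, N2=20)
    mc.run_adsorption(surface_small, cells, params)
    base = cells.positions.copy()
    r0 = mc.run_desorption(surface_small, cells, params, 0.0)
    assert r0.frac1 > 95.0 and r0.frac2 > 95.0
    cells.positions[:] = base
    r_big = mc.run_desorption(surface_small, cells, params, 4.0)
    assert r_big.frac1 < 5.0 and r_big.frac2 < 5.0
    surface_small.swollen = False


def test_separation_factor_sim_examples():
    sf, ok = mc.separation_factor_sim(35.0, 3.0)
    assert ok and sf == pytest.approx(11.67, abs=0.01)
    assert mc.separation_factor_sim(10.0, 10.0)[0] == 1.0
    sf20, _ = mc.separation_factor_sim(35.0, 2.5)
    assert sf20 / sf == pytest.approx(1.2, abs=0.01)
    nan_sf, defined = mc.separation_factor_sim(5.0, 0.0)
    assert not defined and math.isnan(nan_sf)
    with pytest.raises(ValueError):
        mc.separation_factor_sim(-1.0, 2.0)


def test_sweep_ordering_and_monotonicity(mc_sweep_result):
    """Type-1 curve dominates type-2; fractions fall with B_p (within noise)."""
    sw = mc_sweep_result
    assert np.all(sw.frac1 >= sw.frac2 - 1e-9)
    for i in range(len(sw.D_d)):
        f1 = sw.frac1[i]
        tol = 2.0 * np.maximum(sw.frac1_se[i][:-1], 1.0)
        assert np.all(np.diff(f1) <= tol)


def test_reproducibility_same_seed():
    params = mc.MCParams(seed=8, adsorption_steps=50_000)
    outs = []
    for _ in range(2):
        surf = mc.place_domains_rsa(120.0, 0.5, 0.48, seed=31)
        cells = mc.initialize_cells(surf, params, N1=10, N2=10)
        mc.run_adsorption(surf, cells, params)
        outs.append(cells.positions.copy())
    assert np.array_equal(outs[0], outs[1])
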