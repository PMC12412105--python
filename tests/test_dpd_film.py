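"""DPD engine: thermostat, equation of state, topology builders, cross-linking."""

import math

import numpy as np
import pytest

from thermosort import dpd_film as dpd


def test_free_streaming():
    """All forces off: positions advance ballistically by v dt n."""
    sys = dpd.make_fluid(box=(8.0, 8.0, 8.0), rho_b=0.5, a_ii=0.0, seed=1)
    sys.gamma = 0.0
    p0 = sys.pos.copy()
    v0 = sys.vel.copy()
    n = 50
    dpd.integrate(sys, n)
    drift = sys.pos - p0
    drift -= np.round(drift / 8.0) * 8.0
    expected = v0 * sys.dt * n
    expected -= np.round(expected / 8.0) * 8.0
    assert np.allclose(drift, expected, atol=1e-9)


def test_thermostat_holds_set_point(dpd_fluid_rho3):
    _, stats = dpd_fluid_rho3
    assert stats.temperatures.mean() == pytest.approx(1.0, rel=0.03)


def test_fluctuation_dissipation_amplitude():
    sys = dpd.make_fluid(seed=0)
    assert sys.sigma_noise**2 == pytest.approx(2.0 * sys.gamma * sys.kT)


def test_equation_of_state(dpd_fluid_rho5):
    """Virial pressure matches p = rho kT + 0.101 a rho^2 at rho = 5."""
    _, stats = dpd_fluid_rho5
    expected = 5.0 * 1.0 + 0.101 * 25.0 * 25.0
    assert stats.pressure == pytest.approx(expected, rel=0.05)


def test_momentum_conservation(dpd_fluid_rho3):
    """Pairwise forces sum to zero: total momentum stays at machine precision."""
    sys, _ = dpd_fluid_rho3
    P = sys.vel.sum(axis=0)
    assert np.abs(P).max() < 1e-9 * sys.N


def test_instability_detected():
    sys = dpd.make_fluid(box=(6.0, 6.0, 6.0), seed=2)
    sys.dt = 5.0
    with pytest.raises(dpd.IntegrationError):
        dpd.integrate(sys, 50)


# --------------------------------------------------------------------------- #
# topology builders
# --------------------------------------------------------------------------- #


def test_grafted_chain_count_and_determinism():
    spec = dpd.NetworkSpec(n_beads=5, rho_g=0.2, box=(20.0, 20.0, 8.0), seed=3)
    sys = dpd.build_grafted_matrix(spec)
    assert len(sys.anchor_idx) == 80  # 0.2 * 20 * 20
    sys2 = dpd.build_grafted_matrix(spec)
    assert np.array_equal(sys.pos, sys2.pos)
    assert np.array_equal(sys.types, sys2.types)
    with pytest.raises(ValueError):
        dpd.build_grafted_matrix(
            dpd.NetworkSpec(n_beads=200, rho_g=2.0, box=(6.0, 6.0, 6.0))
        )


def test_collapse_reduces_height():
    """Above-LCST equilibration compacts the matrix from a loose start."""
    spec = dpd.NetworkSpec(n_beads=30, rho_g=0.2, box=(7.0, 7.0, 20.0), seed=4)
    sys = dpd.build_grafted_matrix(spec)
    h0 = dpd.matrix_height(sys)
    dpd.integrate(sys, 2500)
    assert dpd.matrix_height(sys) < h0


def test_solvent_quality_switch_involution():
    sys = dpd.build_grafted_matrix(
        dpd.NetworkSpec(n_beads=5, rho_g=0.1, box=(6.0, 6.0, 8.0), seed=5)
    )
    a0 = sys.a_matrix.copy()
    dpd.set_solvent_quality(sys, "belowLCST")
    assert sys.a_matrix[dpd.PNIPAM, dpd.WATER] != a0[dpd.PNIPAM, dpd.WATER]
    assert sys.a_matrix[dpd.WATER, dpd.WATER] == a0[dpd.WATER, dpd.WATER]
    dpd.set_solvent_quality(sys, "aboveLCST")
    assert np.array_equal(sys.a_matrix, a0)
    with pytest.raises(ValueError):
        dpd.set_solvent_quality(sys, "tepid")


def test_matrix_height_first_moment_identities():
    """Uniform slab of thickness t gives h = t; delta layer at c gives 2c."""
    rng = np.random.default_rng(0)
    n = 1000
    sys = dpd.make_fluid(box=(8.0, 8.0, 16.0), rho_b=1.5, seed=6)
    sys.types[:n] = dpd.PNIPAM
    sys.pos[:n, 2] = np.linspace(0.0, 6.0, n)  # uniform slab [0, 6]
    assert dpd.matrix_height(sys) == pytest.approx(6.0, rel=0.01)
    sys.pos[:n, 2] = 3.3
    assert dpd.matrix_height(sys) == pytest.approx(6.6)


def test_coil_globule_response():
    """A free chain is larger below the LCST than above it."""
    def rg(below):
        spec = dpd.NetworkSpec(n_beads=25, rho_g=0.03, gma_fraction=0.0,
                               box=(6.0, 6.0, 12.0), seed=7)
        sys = dpd.build_grafted_matrix(spec)
        if below:
            dpd.set_solvent_quality(sys, "belowLCST")
        dpd.integrate(sys, 2500)
        m = sys.matrix_mask()
        p = sys.pos[m]
        return float(np.sqrt(((p - p.mean(0)) ** 2).sum(1).mean()))

    assert rg(True) > rg(False)


# --------------------------------------------------------------------------- #
# cross-linking
# --------------------------------------------------------------------------- #


def test_crosslink_probability_bernoulli():
    """An isolated overlapping active pair bonds with frequency 0.10 +- 0.01."""
    spec = dpd.NetworkSpec(n_beads=2, rho_g=0.025, gma_fraction=1.0,
                           nu_cr_target=100.0, p_crosslink=0.1,
                           box=(20.0, 20.0, 5.0), seed=8)
    formed = 0
    trials = 0
    for rep in range(120):
        sys = dpd.build_grafted_matrix(
            dpd.NetworkSpec(**{**spec.__dict__, "seed": rep})
        )
        # each chain's two beads overlap; the chains sit far apart so no
        # cross-pair contact can form within the single attempted step
        n_pairs = len(sys.anchor_idx)
        for k, i0 in enumerate(sys.anchor_idx):
            sys.pos[i0] = (2.0 * k + 0.5, 10.0, 1.0)
            sys.pos[i0 + 1] = (2.0 * k + 0.5, 10.0, 1.4)
        sys.vel[:] = 0.0
        nb0 = sys.n_crosslinks()
        stats = dpd.crosslink(sys, spec, 1)
        formed += sys.n_crosslinks() - nb0
        trials += n_pairs
    assert trials >= 1000
    assert formed / trials == pytest.approx(0.10, abs=0.015)


def test_crosslink_trace_saturates(crosslink_run):
    """N_b(t) is non-decreasing and the last 10% of steps add < 1% of bonds."""
    _, stats = crosslink_run
    nb = stats.nb_trace
    assert np.all(np.diff(nb) >= 0)
    tail = len(nb) // 10
    assert nb[-1] - nb[-tail] <= max(0.01 * nb[-1], 1)


def test_nu_cr_accounting_identity(crosslink_run):
    sys, _ = crosslink_run
    n_matrix = int(np.sum((sys.types == dpd.PNIPAM) | (sys.types == dpd.GMA)))
    assert sys.nu_cr() == pytest.approx(200.0 * sys.n_crosslinks() / n_matrix)


def test_crosslink_each_bead_at_most_once(crosslink_run):
    sys, _ = crosslink_run
    xl = sys.bonds[: sys._n_bonds][sys.bond_kind[: sys._n_bonds] == 1]
    flat = xl.ravel()
    assert len(np.unique(flat)) == len(flat)


def test_crosslink_target_converts_leftover_gma():
    spec = dpd.NetworkSpec(n_beads=20, rho_g=0.3, nu_cr_target=4.0,
                           box=(7.0, 7.0, 12.0), seed=9)
    sys = dpd.build_grafted_matrix(spec)
    dpd.integrate(sys, 300)
    dpd.crosslink(sys, spec, 800)
    assert sys.nu_cr() == pytest.approx(4.0, abs=0.4)
    assert not np.any(sys.active)
    assert np.sum(sys.types == dpd.GMA) == 2 * sys.n_crosslinks()


# --------------------------------------------------------------------------- #
# cap-pinned geometry
# --------------------------------------------------------------------------- #


def test_cap_pins_respect_height_limit():
    cap = dpd.CapPinSpec(R=12.0, cap_height=5.0, pin_height=3.5, separation=6.0,
                         rho_pd=0.6, box_y=4.0, box_z=14.0)
    net = dpd.NetworkSpec(n_beads=20, rho_g=0.2, seed=10)
    sys = dpd.build_cap_pinned_matrix(cap, net)
    n_substrate = np.sum(sys.anchor_pos[:, 2] == 0.0)
    pins = sys.anchor_pos[sys.anchor_pos[:, 2] > 0.0]
    assert len(pins) > 0
    assert np.all(pins[:, 2] <= cap.pin_height + 1e-9)
    assert n_substrate > 0


def test_cap_zero_pin_density():
    cap = dpd.CapPinSpec(R=12.0, cap_height=5.0, pin_height=3.5, separation=6.0,
                         rho_pd=0.0, box_y=4.0, box_z=14.0)
    net = dpd.NetworkSpec(n_beads=20, rho_g=0.2, seed=11)
    sys = dpd.build_cap_pinned_matrix(cap, net)
    assert np.all(sys.anchor_pos[:, 2] == 0.0)  # substrate grafts only


def test_cap_overlap_rejected():
    with pytest.raises(ValueError):
        dpd.build_cap_pinned_matrix(
            dpd.CapPinSpec(separation=0.0), dpd.NetworkSpec(n_beads=10)
        )


# --------------------------------------------------------------------------- #
# phase separation
# --------------------------------------------------------------------------- #


def test_phase_separation_domain_growth_with_f():
    """Mean PGMA cluster size and height grow with the PGMA mass fraction."""
    out = {}
    for f in (0.15, 0.4):
        _, fits, clusters = dpd.phase_separation_experiment(
            f, n_steps=3500, box=(14.0, 14.0, 10.0), n_beads=16,
            graft_density=0.5, seed=12,
        )
        sizes = [len(c) for c in clusters]
        out[f] = (np.mean(sizes) if sizes else 0.0, len(clusters))
    assert out[0.4][0] > out[0.15][0]
    assert out[0.15][1] >= 1  # dilute limit still yields isolated clusters


def test_phase_separation_cap_fit_consistency():
    """Cap radii fitted from alternate slices agree within 10%-ish."""
    sys, fits, clusters = dpd.phase_separation_experiment(
        0.4, n_steps=3500, box=(14.0, 14.0, 10.0), n_beads=16,
        graft_density=0.5, seed=13,
    )
    assert fits, "expected at least one well-formed domain"
    big = max(clusters, key=len)
    full = dpd._fit_cluster_cap(sys.pos[big], sys.box[0], sys.box[1])
    assert full is not None and full.H > 0
    with pytest.raises(ValueError):
        dpd.phase_separation_experiment(1.5, n_steps=10)
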