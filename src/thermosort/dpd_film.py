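"""Dissipative particle dynamics of grafted, cross-linkable thermoresponsive films.

Coarse-grained model of the polymer coatings: repeating units of PGMA and
PNIPAM(-co-GMA) are soft beads (~10 heavy atoms each), water is explicit
solvent beads, and the substrate is a frozen wall-bead layer with bounce-back
reflection.  Standard DPD forces act between beads within ``r_c = 1``: a soft
conservative repulsion ``a_ij (1 - r)``, and the pairwise
dissipative/random thermostat with ``sigma^2 = 2 gamma kT`` (fluctuation-
dissipation).  Chains are strings of harmonic bonds; grafts and pins are
harmonic springs to fixed anchor sites.  Integration uses the modified
velocity-Verlet scheme with prediction parameter ``lambda``.

The LCST switch of the thermoresponsive matrix is a force-field switch:
``a(PNIPAM, WATER)`` takes the good-solvent value below the LCST and a
poor-solvent value above it; no explicit temperature model is attempted.

Cross-linking is stochastic: GMA beads start "active", and an overlapping
active pair bonds with probability 0.1 per step; both partners then become
inert.  The cross-link fraction is ``nu_cr = 2 N_b / N_matrix * 100`` with
``N_b`` formed bonds and ``N_matrix`` the total matrix bead count.

Default force-field numbers are the standard DPD water-like parameterisation
(``rho_b = 3``, ``a_ii = 25``, ``gamma = 4.5``, ``dt = 0.04``,
``lambda = 0.65``) with ``a(PGMA, PNIPAM) = 40`` for strong incompatibility and
``a(PGMA, WATER) = 27`` (near-theta).  The solvent-quality contrast of the
matrix, ``a(PNIPAM, WATER) = 17 / 50`` below/above the LCST, is the one
calibrated pair: it sets the magnitude of the brush collapse and was chosen
to reproduce the observed swelling ratios of surface-grafted PNIPAM-co-GMA;
all entries are exposed on the system objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .capgeom import SphericalCap

__all__ = [
    "PGMA",
    "PNIPAM",
    "GMA",
    "WATER",
    "WALL",
    "DPDSystem",
    "NetworkSpec",
    "CapPinSpec",
    "SwellingResult",
    "IntegrateStats",
    "default_force_field",
    "make_fluid",
    "build_grafted_matrix",
    "integrate",
    "crosslink",
    "set_solvent_quality",
    "matrix_height",
    "swelling_experiment",
    "build_cap_pinned_matrix",
    "phase_separation_experiment",
    "kinetic_temperature",
]

PGMA, PNIPAM, GMA, WATER, WALL = 0, 1, 2, 3, 4

_A_GOOD = 17.0  # PNIPAM-water below LCST (strongly hydrated, swollen)
_A_POOR = 50.0  # PNIPAM-water above LCST (dehydrated, collapsed)
_A_THETA = 27.0  # PGMA-water, near-theta
_A_INCOMPAT = 40.0  # PGMA-PNIPAM strong repulsion


class IntegrationError(RuntimeError):
    """Raised when bead velocities overflow (unstable timestep)."""


def default_force_field(below_lcst: bool = False) -> np.ndarray:
    """5x5 conservative repulsion matrix ``a_ij`` for (PGMA, PNIPAM, GMA, WATER, WALL).

    GMA beads interact like PNIPAM (the epoxy unit is a minority comonomer);
    the wall is neutral (``a = 25``) to everything.
    """
    a = np.full((5, 5), 25.0)
    for p in (PNIPAM, GMA):
        a[PGMA, p] = a[p, PGMA] = _A_INCOMPAT
        a[p, WATER] = a[WATER, p] = _A_GOOD if below_lcst else _A_POOR
    a[PGMA, WATER] = a[WATER, PGMA] = _A_THETA
    return a


@dataclass
class DPDSystem:
    """Bead-spring DPD system in a box periodic in x, y with z walls.

    ``frozen`` marks immobile beads (substrate/ceiling wall layers, solid
    caps).  ``bonds`` is an edge list; ``bond_kind`` labels each edge
    (0 backbone, 1 cross-link, 2 graft-to-substrate, 3 pin-to-cap; anchored
    springs to fixed sites are held separately in ``anchor_idx/anchor_pos``).
    """

    pos: np.ndarray
    vel: np.ndarray
    types: np.ndarray
    frozen: np.ndarray
    box: tuple[float, float, float]
    a_matrix: np.ndarray
    bonds: np.ndarray
    bond_kind: np.ndarray
    anchor_idx: np.ndarray
    anchor_pos: np.ndarray
    active: np.ndarray  # cross-linkable flags
    gamma: float = 4.5
    kT: float = 1.0
    dt: float = 0.04
    lam: float = 0.65
    bond_k: float = 4.0
    periodic_z: bool = False
    below_lcst: bool = False
    seed: int = 0
    _rng: np.random.Generator = field(default=None, repr=False)

    def __post_init__(self):
        if self._rng is None:
            self._rng = np.random.default_rng(self.seed)

    @property
    def N(self) -> int:
        return len(self.types)

    @property
    def n_mobile(self) -> int:
        return int(np.sum(~self.frozen))

    @property
    def sigma_noise(self) -> float:
        """Random-force amplitude from fluctuation-dissipation."""
        return math.sqrt(2.0 * self.gamma * self.kT)

    def matrix_mask(self) -> np.ndarray:
        """Mobile PNIPAM/GMA beads: the thermoresponsive matrix."""
        return (~self.frozen) & ((self.types == PNIPAM) | (self.types == GMA))

    def n_crosslinks(self) -> int:
        return int(np.sum(self.bond_kind == 1))

    def nu_cr(self) -> float:
        """Cross-link fraction: 2 N_b / N_matrix * 100 (percent)."""
        nm = int(np.sum((self.types == PNIPAM) | (self.types == GMA)) )
        return 200.0 * self.n_crosslinks() / max(nm, 1)


@dataclass
class NetworkSpec:
    """Grafted PNIPAM-co-GMA network: chains, grafting and cross-linking.

    ``n_beads`` is beads per chain; ``gma_fraction`` the fraction of chain
    beads that start as cross-linkable GMA (0.30 in the cross-linking stage);
    ``nu_cr_target`` the cross-link fraction to stop at (percent);
    ``p_crosslink`` the per-step bonding probability for an overlapping active
    pair.
    """

    n_beads: int = 100
    rho_g: float = 0.2
    gma_fraction: float = 0.30
    nu_cr_target: float = 6.0
    p_crosslink: float = 0.1
    box: tuple[float, float, float] = (10.0, 10.0, 40.0)
    rho_b: float = 3.0
    seed: int = 0


@dataclass
class CapPinSpec:
    """Geometry of the two-cap pinned-matrix simulation box.

    Two frozen spherical-cap obstacles sit at opposite box sides (their
    periodic images form the domain array); ``separation`` is the distance
    between nearest cap points at substrate level, ``pin_height`` the maximal
    height at which matrix chains may be pinned to the cap surface,
    ``rho_pd`` the pin density per unit cap area.
    """

    R: float = 30.0
    cap_height: float = 10.0
    pin_height: float = 7.0
    separation: float = 20.0
    rho_pd: float = 0.2
    box_y: float = 5.0
    box_z: float = 25.0

    def base_half_width(self) -> float:
        return math.sqrt(self.R**2 - (self.R - self.cap_height) ** 2)


@dataclass
class SwellingResult:
    """Heights of the matrix below (h1) and above (h2) the LCST."""

    h1: float
    h2: float
    h1_se: float
    h2_se: float
    nu_cr: float
    equilibrated: bool
    heights_trace_h1: np.ndarray
    heights_trace_h2: np.ndarray

    @property
    def ratio(self) -> float:
        return self.h1 / self.h2

    @property
    def ratio_se(self) -> float:
        r = self.ratio
        return abs(r) * math.sqrt(
            (self.h1_se / self.h1) ** 2 + (self.h2_se / self.h2) ** 2
        )


@dataclass
class IntegrateStats:
    """Per-burst integration diagnostics."""

    temperatures: np.ndarray
    pressure: float
    nb_trace: np.ndarray


# --------------------------------------------------------------------------- #
# numba core
# --------------------------------------------------------------------------- #


@njit(cache=True, fastmath=True)
def _dpd_run(
    pos, vel, typ, frozen, a_mat,
    bonds, bond_kind, n_bonds, bond_k,
    anc_idx, anc_pos,
    Lx, Ly, Lz, periodic_z,
    gamma, sigma, kT, dt, lam,
    n_steps, sample_every, seed,
    active, p_cross, nb_target, do_cross,
):
    """Advance n_steps of DPD; optionally attempt cross-linking each step.

    Returns (temps, mean conservative virial, nb_trace, n_bonds_new, err_step).
    Bond arrays are mutated in place (capacity preallocated by the caller).
    """
    np.random.seed(seed)
    N = pos.shape[0]
    inv_sqrt_dt = 1.0 / math.sqrt(dt)

    if periodic_z:
        zlo = 0.0
        zhi = Lz
    else:
        zlo = -1.5
        zhi = Lz + 1.5
    ncx = max(int(Lx), 1)
    ncy = max(int(Ly), 1)
    ncz = max(int(zhi - zlo), 1)
    cwx = Lx / ncx
    cwy = Ly / ncy
    cwz = (zhi - zlo) / ncz
    ncells = ncx * ncy * ncz

    f = np.zeros((N, 3))
    f_prev = np.zeros((N, 3))
    cell_of = np.empty(N, np.int64)
    start = np.empty(ncells + 1, np.int64)
    order = np.empty(N, np.int64)

    n_mobile = 0
    for i in range(N):
        if not frozen[i]:
            n_mobile += 1

    n_samp = n_steps // sample_every + 1
    temps = np.zeros(n_samp)
    n_temp = 0
    virial_acc = 0.0
    n_virial = 0
    nb_trace = np.zeros(n_steps, np.int64)
    cand_i = np.empty(4 * N, np.int64)
    cand_j = np.empty(4 * N, np.int64)

    # half-neighbour stencil: 13 offsets + self-cell
    offs = np.array(
        [
            [1, 0, 0], [-1, 1, 0], [0, 1, 0], [1, 1, 0],
            [-1, -1, 1], [0, -1, 1], [1, -1, 1],
            [-1, 0, 1], [0, 0, 1], [1, 0, 1],
            [-1, 1, 1], [0, 1, 1], [1, 1, 1],
        ],
        np.int64,
    )

    err_step = -1

    for step in range(-1, n_steps):
        # step -1 computes initial forces only
        if step >= 0:
            # predictor + position update
            for i in range(N):
                if frozen[i]:
                    continue
                for d in range(3):
                    pos[i, d] += dt * vel[i, d] + 0.5 * dt * dt * f[i, d]
                    vel[i, d] += lam * dt * f[i, d]  # prediction stored in vel
                # wrap / reflect
                if pos[i, 0] >= Lx:
                    pos[i, 0] -= Lx
                elif pos[i, 0] < 0.0:
                    pos[i, 0] += Lx
                if pos[i, 1] >= Ly:
                    pos[i, 1] -= Ly
                elif pos[i, 1] < 0.0:
                    pos[i, 1] += Ly
                if periodic_z:
                    if pos[i, 2] >= Lz:
                        pos[i, 2] -= Lz
                    elif pos[i, 2] < 0.0:
                        pos[i, 2] += Lz
                else:
                    if pos[i, 2] < 0.0:
                        pos[i, 2] = -pos[i, 2]
                        vel[i, 0] = -vel[i, 0]
                        vel[i, 1] = -vel[i, 1]
                        vel[i, 2] = -vel[i, 2]
                    elif pos[i, 2] > Lz:
                        pos[i, 2] = 2.0 * Lz - pos[i, 2]
                        vel[i, 0] = -vel[i, 0]
                        vel[i, 1] = -vel[i, 1]
                        vel[i, 2] = -vel[i, 2]

        # ----- cell list -----
        for i in range(N):
            # indices clamped: a diverging trajectory (unstable dt) must reach
            # the velocity-overflow check below without corrupting the grid
            cx = int(pos[i, 0] / cwx)
            if cx >= ncx:
                cx = ncx - 1
            elif cx < 0:
                cx = 0
            cy = int(pos[i, 1] / cwy)
            if cy >= ncy:
                cy = ncy - 1
            elif cy < 0:
                cy = 0
            cz = int((pos[i, 2] - zlo) / cwz)
            if cz < 0:
                cz = 0
            elif cz >= ncz:
                cz = ncz - 1
            cell_of[i] = (cz * ncy + cy) * ncx + cx
        start[:] = 0
        for i in range(N):
            start[cell_of[i] + 1] += 1
        for c in range(ncells):
            start[c + 1] += start[c]
        fill = start.copy()
        for i in range(N):
            order[fill[cell_of[i]]] = i
            fill[cell_of[i]] += 1

        # ----- forces -----
        for i in range(N):
            f[i, 0] = 0.0
            f[i, 1] = 0.0
            f[i, 2] = 0.0
        virial = 0.0
        for cz in range(ncz):
            for cy in range(ncy):
                for cx in range(ncx):
                    c = (cz * ncy + cy) * ncx + cx
                    s0 = start[c]
                    e0 = start[c + 1]
                    # intra-cell pairs + half-stencil neighbour cells
                    # (o = -1 marks the intra-cell pass; the pair body is
                    # written out inline — a helper call here defeats LLVM's
                    # optimisation of this innermost loop)
                    for o in range(-1, 13):
                        if o < 0:
                            c2 = c
                        else:
                            nx = cx + offs[o, 0]
                            ny = cy + offs[o, 1]
                            nz = cz + offs[o, 2]
                            if nx < 0:
                                nx += ncx
                            elif nx >= ncx:
                                nx -= ncx
                            if ny < 0:
                                ny += ncy
                            elif ny >= ncy:
                                ny -= ncy
                            if nz < 0 or nz >= ncz:
                                if periodic_z:
                                    nz = nz % ncz
                                else:
                                    continue
                            c2 = (nz * ncy + ny) * ncx + nx
                        s2 = start[c2]
                        e2 = start[c2 + 1]
                        for ii in range(s0, e0):
                            i = order[ii]
                            xi0 = pos[i, 0]
                            xi1 = pos[i, 1]
                            xi2 = pos[i, 2]
                            jj0 = ii + 1 if o < 0 else s2
                            for jj in range(jj0, e2):
                                j = order[jj]
                                dx = xi0 - pos[j, 0]
                                if dx > 0.5 * Lx:
                                    dx -= Lx
                                elif dx < -0.5 * Lx:
                                    dx += Lx
                                dy = xi1 - pos[j, 1]
                                if dy > 0.5 * Ly:
                                    dy -= Ly
                                elif dy < -0.5 * Ly:
                                    dy += Ly
                                dz = xi2 - pos[j, 2]
                                if periodic_z:
                                    if dz > 0.5 * Lz:
                                        dz -= Lz
                                    elif dz < -0.5 * Lz:
                                        dz += Lz
                                r2 = dx * dx + dy * dy + dz * dz
                                if r2 < 1.0 and r2 > 1e-12:
                                    if frozen[i] and frozen[j]:
                                        continue
                                    r = math.sqrt(r2)
                                    inv_r = 1.0 / r
                                    w = 1.0 - r
                                    ex = dx * inv_r
                                    ey = dy * inv_r
                                    ez = dz * inv_r
                                    fc = a_mat[typ[i], typ[j]] * w
                                    ev = (
                                        ex * (vel[i, 0] - vel[j, 0])
                                        + ey * (vel[i, 1] - vel[j, 1])
                                        + ez * (vel[i, 2] - vel[j, 2])
                                    )
                                    fd = -gamma * w * w * ev
                                    # sqrt(12)-scaled uniform: unit-variance noise
                                    fr = (
                                        sigma * w * inv_sqrt_dt
                                        * 3.4641016151377544
                                        * (np.random.random() - 0.5)
                                    )
                                    ft = fc + fd + fr
                                    f[i, 0] += ft * ex
                                    f[i, 1] += ft * ey
                                    f[i, 2] += ft * ez
                                    f[j, 0] -= ft * ex
                                    f[j, 1] -= ft * ey
                                    f[j, 2] -= ft * ez
                                    virial += fc * r
        # bonds (harmonic, natural length 0)
        for b in range(n_bonds):
            i = bonds[b, 0]
            j = bonds[b, 1]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if dx > 0.5 * Lx:
                dx -= Lx
            elif dx < -0.5 * Lx:
                dx += Lx
            if dy > 0.5 * Ly:
                dy -= Ly
            elif dy < -0.5 * Ly:
                dy += Ly
            if periodic_z:
                if dz > 0.5 * Lz:
                    dz -= Lz
                elif dz < -0.5 * Lz:
                    dz += Lz
            f[i, 0] -= bond_k * dx
            f[i, 1] -= bond_k * dy
            f[i, 2] -= bond_k * dz
            f[j, 0] += bond_k * dx
            f[j, 1] += bond_k * dy
            f[j, 2] += bond_k * dz
        # anchors
        for b in range(len(anc_idx)):
            i = anc_idx[b]
            dx = pos[i, 0] - anc_pos[b, 0]
            dy = pos[i, 1] - anc_pos[b, 1]
            dz = pos[i, 2] - anc_pos[b, 2]
            if dx > 0.5 * Lx:
                dx -= Lx
            elif dx < -0.5 * Lx:
                dx += Lx
            if dy > 0.5 * Ly:
                dy -= Ly
            elif dy < -0.5 * Ly:
                dy += Ly
            f[i, 0] -= bond_k * dx
            f[i, 1] -= bond_k * dy
            f[i, 2] -= bond_k * dz

        if step >= 0:
            # corrector
            ke = 0.0
            vmax2 = 0.0
            for i in range(N):
                if frozen[i]:
                    continue
                for d in range(3):
                    # vel currently holds the lambda-prediction; recover and correct
                    v0 = vel[i, d] - lam * dt * f_prev[i, d]
                    vnew = v0 + 0.5 * dt * (f_prev[i, d] + f[i, d])
                    vel[i, d] = vnew
                v2 = vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
                ke += v2
                if v2 != v2:  # NaN also trips the overflow guard
                    vmax2 = 1e30
                elif v2 > vmax2:
                    vmax2 = v2
            if vmax2 > 2500.0:
                err_step = step
                break
            if step % sample_every == 0:
                temps[n_temp] = ke / (3.0 * n_mobile)
                n_temp += 1
                virial_acc += virial
                n_virial += 1

            # ----- cross-linking attempts -----
            if do_cross and n_bonds < nb_target:
                ncand = 0
                for c in range(ncells):
                    for ii in range(start[c], start[c + 1]):
                        i = order[ii]
                        if not active[i]:
                            continue
                        # same cell
                        for jj in range(ii + 1, start[c + 1]):
                            j = order[jj]
                            if active[j] and _within_rc(
                                pos, i, j, Lx, Ly, Lz, periodic_z
                            ):
                                if ncand < len(cand_i):
                                    cand_i[ncand] = i
                                    cand_j[ncand] = j
                                    ncand += 1
                        cz = c // (ncx * ncy)
                        cy = (c // ncx) % ncy
                        cx = c % ncx
                        for o in range(13):
                            nx = cx + offs[o, 0]
                            ny = cy + offs[o, 1]
                            nz = cz + offs[o, 2]
                            if nx < 0:
                                nx += ncx
                            elif nx >= ncx:
                                nx -= ncx
                            if ny < 0:
                                ny += ncy
                            elif ny >= ncy:
                                ny -= ncy
                            if nz < 0 or nz >= ncz:
                                if periodic_z:
                                    nz = nz % ncz
                                else:
                                    continue
                            c2 = (nz * ncy + ny) * ncx + nx
                            for jj in range(start[c2], start[c2 + 1]):
                                j = order[jj]
                                if active[j] and _within_rc(
                                    pos, i, j, Lx, Ly, Lz, periodic_z
                                ):
                                    if ncand < len(cand_i):
                                        cand_i[ncand] = i
                                        cand_j[ncand] = j
                                        ncand += 1
                # randomized order; a bead consumed this step is skipped later
                for k in range(ncand - 1, 0, -1):
                    m = np.random.randint(0, k + 1)
                    ti = cand_i[k]; cand_i[k] = cand_i[m]; cand_i[m] = ti
                    tj = cand_j[k]; cand_j[k] = cand_j[m]; cand_j[m] = tj
                for k in range(ncand):
                    if n_bonds >= nb_target:
                        break
                    i = cand_i[k]
                    j = cand_j[k]
                    if active[i] and active[j] and np.random.random() < p_cross:
                        bonds[n_bonds, 0] = i
                        bonds[n_bonds, 1] = j
                        bond_kind[n_bonds] = 1
                        n_bonds += 1
                        active[i] = False
                        active[j] = False
            nb_trace[step] = n_bonds

        # stash forces for the corrector of the next step
        for i in range(N):
            f_prev[i, 0] = f[i, 0]
            f_prev[i, 1] = f[i, 1]
            f_prev[i, 2] = f[i, 2]

    mean_virial = virial_acc / max(n_virial, 1)
    return temps[:n_temp], mean_virial, nb_trace, n_bonds, err_step


@njit(cache=True, inline="always")
def _within_rc(pos, i, j, Lx, Ly, Lz, periodic_z):
    dx = pos[i, 0] - pos[j, 0]
    dy = pos[i, 1] - pos[j, 1]
    dz = pos[i, 2] - pos[j, 2]
    if dx > 0.5 * Lx:
        dx -= Lx
    elif dx < -0.5 * Lx:
        dx += Lx
    if dy > 0.5 * Ly:
        dy -= Ly
    elif dy < -0.5 * Ly:
        dy += Ly
    if periodic_z:
        if dz > 0.5 * Lz:
            dz -= Lz
        elif dz < -0.5 * Lz:
            dz += Lz
    return dx * dx + dy * dy + dz * dz < 1.0


# --------------------------------------------------------------------------- #
# builders
# --------------------------------------------------------------------------- #


def _wall_layers(Lx: float, Ly: float, Lz: float, rho: float, rng) -> np.ndarray:
    """Frozen wall-bead positions below the substrate and above the ceiling."""
    n = int(round(rho * Lx * Ly))
    bottom = np.column_stack(
        [rng.uniform(0, Lx, n), rng.uniform(0, Ly, n), rng.uniform(-1.0, 0.0, n)]
    )
    top = np.column_stack(
        [rng.uniform(0, Lx, n), rng.uniform(0, Ly, n), rng.uniform(Lz, Lz + 1.0, n)]
    )
    return np.vstack([bottom, top])


def _assemble(
    pos_list, typ_list, frozen_list, box, rng,
    bonds=None, bond_kind=None, anchor_idx=None, anchor_pos=None,
    max_extra_bonds=0, below_lcst=False, seed=0,
) -> DPDSystem:
    pos = np.vstack(pos_list)
    typ = np.concatenate(typ_list).astype(np.int64)
    frozen = np.concatenate(frozen_list).astype(bool)
    N = len(typ)
    vel = np.zeros((N, 3))
    vel[~frozen] = rng.normal(0.0, 1.0, (int(np.sum(~frozen)), 3))
    vel[~frozen] -= vel[~frozen].mean(axis=0)
    nb = 0 if bonds is None else len(bonds)
    cap = nb + max_extra_bonds
    bond_arr = np.zeros((max(cap, 1), 2), np.int64)
    kind_arr = np.zeros(max(cap, 1), np.int64)
    if nb:
        bond_arr[:nb] = bonds
        kind_arr[:nb] = bond_kind
    sys = DPDSystem(
        pos=pos, vel=vel, types=typ, frozen=frozen, box=box,
        a_matrix=default_force_field(below_lcst),
        bonds=bond_arr, bond_kind=kind_arr,
        anchor_idx=(np.empty(0, np.int64) if anchor_idx is None else np.asarray(anchor_idx, np.int64)),
        anchor_pos=(np.empty((0, 3)) if anchor_pos is None else np.asarray(anchor_pos, float)),
        active=np.zeros(N, bool),
        below_lcst=below_lcst,
        seed=seed,
    )
    sys._n_bonds = nb
    return sys


def make_fluid(
    box: tuple[float, float, float] = (8.0, 8.0, 8.0),
    rho_b: float = 3.0,
    a_ii: float = 25.0,
    seed: int = 0,
) -> DPDSystem:
    """Pure solvent in a fully periodic box (thermostat / equation-of-state runs)."""
    rng = np.random.default_rng(seed)
    Lx, Ly, Lz = box
    n = int(round(rho_b * Lx * Ly * Lz))
    pos = rng.uniform(0, 1, (n, 3)) * np.array(box)
    typ = np.full(n, WATER)
    sys = _assemble(
        [pos], [typ], [np.zeros(n, bool)], box, rng, seed=seed,
    )
    sys.a_matrix = np.full((5, 5), a_ii)
    sys.periodic_z = True
    return sys


def _grow_chain(rng, anchor_xy, n_beads, Lx, Ly, Lz, zmax=None) -> np.ndarray:
    """Random walk from the substrate, reflected into the slab [0, zmax].

    Produces a space-filling compact layer rather than a stretched chain, so
    the collapsed pre-equilibration starts close to its target state.
    """
    zhi = Lz - 0.5 if zmax is None else min(zmax, Lz - 0.5)
    p = np.empty((n_beads, 3))
    x, y = anchor_xy
    z = 0.3
    for k in range(n_beads):
        p[k] = (x % Lx, y % Ly, z)
        x += rng.normal(0.0, 0.35)
        y += rng.normal(0.0, 0.35)
        z += rng.normal(0.0, 0.45)
        if z < 0.2:
            z = 0.4 - z
        if z > zhi:
            z = 2.0 * zhi - z
            z = max(z, 0.2)
    return p


def build_grafted_matrix(spec: NetworkSpec) -> DPDSystem:
    """Grafted PNIPAM-co-GMA chains on the substrate, solvent-filled box.

    ``round(rho_g * Lx * Ly)`` chains of ``n_beads`` beads each, first bead
    tethered to a random substrate point by a harmonic anchor; a fraction
    ``gma_fraction`` of beads are cross-linkable GMA.  The solvent is set to
    the above-LCST (poor) state: cross-linking in the experiments happens in
    the collapsed film.
    """
    rng = np.random.default_rng(spec.seed)
    Lx, Ly, Lz = spec.box
    n_chains = int(round(spec.rho_g * Lx * Ly))
    if n_chains * spec.n_beads > 0.7 * spec.rho_b * Lx * Ly * Lz:
        raise ValueError("grafting density exceeds the box capacity")
    chain_pos = []
    bonds = []
    anchor_idx = []
    anchor_pos = []
    idx0 = 0
    # chains start as compact layers near the substrate: cross-linking is done
    # in the collapsed film, so the initial state should already be collapsed
    # (a stretched start would lock an extended network into the cross-links)
    n_poly_total = n_chains * spec.n_beads
    zcap = min(n_poly_total / (spec.rho_b * Lx * Ly) + 2.0, Lz - 1.0)
    for c in range(n_chains):
        axy = (rng.uniform(0, Lx), rng.uniform(0, Ly))
        chain_pos.append(_grow_chain(rng, axy, spec.n_beads, Lx, Ly, Lz, zmax=zcap))
        for k in range(spec.n_beads - 1):
            bonds.append((idx0 + k, idx0 + k + 1))
        anchor_idx.append(idx0)
        anchor_pos.append((axy[0] % Lx, axy[1] % Ly, 0.0))
        idx0 += spec.n_beads
    n_poly = idx0
    typ_poly = np.full(n_poly, PNIPAM)
    n_gma = int(round(spec.gma_fraction * n_poly))
    gma_idx = rng.choice(n_poly, size=n_gma, replace=False)
    typ_poly[gma_idx] = GMA

    n_solv = int(round(spec.rho_b * Lx * Ly * Lz)) - n_poly
    solv = rng.uniform(0, 1, (max(n_solv, 0), 3)) * np.array([Lx, Ly, Lz])
    walls = _wall_layers(Lx, Ly, Lz, spec.rho_b, rng)

    sys = _assemble(
        [np.vstack(chain_pos), solv, walls],
        [typ_poly, np.full(len(solv), WATER), np.full(len(walls), WALL)],
        [np.zeros(n_poly, bool), np.zeros(len(solv), bool), np.ones(len(walls), bool)],
        spec.box, rng,
        bonds=np.array(bonds, np.int64), bond_kind=np.zeros(len(bonds), np.int64),
        anchor_idx=anchor_idx, anchor_pos=anchor_pos,
        max_extra_bonds=n_poly // 2 + 1,
        below_lcst=False,
        seed=spec.seed,
    )
    sys.active[:n_poly] = typ_poly == GMA
    return sys


# --------------------------------------------------------------------------- #
# operations
# --------------------------------------------------------------------------- #


def integrate(
    system: DPDSystem, n_steps: int, sample_every: int = 25
) -> IntegrateStats:
    """Advance standard DPD dynamics with the modified velocity-Verlet scheme.

    Returns sampled kinetic temperatures and the virial pressure
    ``p = rho kT + <sum r.F_C> / (3 V)`` (conservative contribution only,
    meaningful for homogeneous fluids).
    """
    seed = int(system._rng.integers(2**31 - 1))
    temps, virial, _, _, err = _dpd_run(
        system.pos, system.vel, system.types, system.frozen, system.a_matrix,
        system.bonds, system.bond_kind, system._n_bonds, system.bond_k,
        system.anchor_idx, system.anchor_pos,
        system.box[0], system.box[1], system.box[2], system.periodic_z,
        system.gamma, system.sigma_noise, system.kT, system.dt, system.lam,
        n_steps, sample_every, seed,
        system.active, 0.0, 0, False,
    )
    if err >= 0:
        raise IntegrationError(f"bead velocity overflow at step {err}; reduce dt")
    V = system.box[0] * system.box[1] * system.box[2]
    rho = system.n_mobile / V
    pressure = rho * system.kT + virial / (3.0 * V)
    return IntegrateStats(temperatures=temps, pressure=pressure, nb_trace=np.empty(0, np.int64))


def crosslink(
    system: DPDSystem, spec: NetworkSpec, n_steps: int, sample_every: int = 25
) -> IntegrateStats:
    """Run dynamics with stochastic cross-linking of active GMA beads.

    Each step, overlapping active pairs bond with probability
    ``spec.p_crosslink`` in randomized order; both partners become inert.
    Linking stops at the bond count matching ``spec.nu_cr_target``; remaining
    unreacted GMA beads are then converted to PNIPAM.  Returns the bond-count
    trace ``N_b(t)``.
    """
    n_matrix = int(np.sum((system.types == PNIPAM) | (system.types == GMA)))
    nb_target = system._n_bonds + max(
        int(round(spec.nu_cr_target * n_matrix / 200.0)) - system.n_crosslinks(), 0
    )
    if nb_target > len(system.bonds):
        raise ValueError("bond capacity too small for the requested nu_cr")
    seed = int(system._rng.integers(2**31 - 1))
    temps, _, nb_trace, n_bonds, err = _dpd_run(
        system.pos, system.vel, system.types, system.frozen, system.a_matrix,
        system.bonds, system.bond_kind, system._n_bonds, system.bond_k,
        system.anchor_idx, system.anchor_pos,
        system.box[0], system.box[1], system.box[2], system.periodic_z,
        system.gamma, system.sigma_noise, system.kT, system.dt, system.lam,
        n_steps, sample_every, seed,
        system.active, spec.p_crosslink, nb_target, True,
    )
    if err >= 0:
        raise IntegrationError(f"bead velocity overflow at step {err}; reduce dt")
    system._n_bonds = int(n_bonds)
    if system.n_crosslinks() >= int(round(spec.nu_cr_target * n_matrix / 200.0)):
        # target reached: unreacted cross-linker units behave as plain PNIPAM
        system.types[system.active] = PNIPAM
        system.active[:] = False
    return IntegrateStats(temperatures=temps, pressure=float("nan"), nb_trace=nb_trace)


def set_solvent_quality(system: DPDSystem, regime: str) -> DPDSystem:
    """Switch the matrix-solvent interaction across the LCST.

    ``belowLCST`` is the good-solvent (swollen) state, ``aboveLCST`` the
    poor-solvent (collapsed) state.  Only the PNIPAM/GMA-water entries change.
    """
    if regime == "belowLCST":
        val, flag = _A_GOOD, True
    elif regime == "aboveLCST":
        val, flag = _A_POOR, False
    else:
        raise ValueError(f"unknown solvent regime {regime!r}")
    for p in (PNIPAM, GMA):
        system.a_matrix[p, WATER] = system.a_matrix[WATER, p] = val
    system.below_lcst = flag
    return system


def matrix_height(system: DPDSystem) -> float:
    """First-moment brush height of the matrix: ``h = 2 <z>`` over matrix beads."""
    mask = system.matrix_mask()
    if not np.any(mask):
        raise ValueError("no matrix beads present")
    return 2.0 * float(system.pos[mask, 2].mean())


def kinetic_temperature(system: DPDSystem) -> float:
    v = system.vel[~system.frozen]
    return float(np.sum(v * v) / (3.0 * len(v)))


def _sample_height(system, n_chunks, steps_per_chunk) -> np.ndarray:
    hs = np.empty(n_chunks)
    for k in range(n_chunks):
        integrate(system, steps_per_chunk)
        hs[k] = matrix_height(system)
    return hs


def _pre_stretch(system: DPDSystem, factor: float) -> None:
    """Affine z-stretch of the matrix beads toward the expected swollen state.

    Brush swelling is Rouse-slow for long chains; relaxing down from a mildly
    over-stretched state reaches the stationary height in a fraction of the
    steps that swelling up from the collapsed state needs.  The soft DPD
    potentials tolerate the transient overlaps this creates.
    """
    m = system.matrix_mask()
    system.pos[m, 2] = np.minimum(system.pos[m, 2] * factor, system.box[2] - 1.0)


def _measure_swelling(
    sys: DPDSystem,
    spec: NetworkSpec,
    collapse_steps: int,
    crosslink_steps: int,
    equil_steps: int,
    sample_chunks: int,
    chunk_steps: int,
    pre_stretch: float,
) -> SwellingResult:
    integrate(sys, collapse_steps)
    crosslink(sys, spec, crosslink_steps)
    integrate(sys, max(equil_steps // 2, 1))
    h2s = _sample_height(sys, sample_chunks, chunk_steps)
    set_solvent_quality(sys, "belowLCST")
    if pre_stretch > 1.0:
        _pre_stretch(sys, pre_stretch)
    integrate(sys, equil_steps)
    h1s = _sample_height(sys, sample_chunks + sample_chunks // 2, chunk_steps)
    h1, h2 = h1s.mean(), h2s.mean()
    se1 = h1s.std(ddof=1) / math.sqrt(len(h1s))
    se2 = h2s.std(ddof=1) / math.sqrt(len(h2s))
    drift = abs(h1s[len(h1s) // 2:].mean() - h1s[: len(h1s) // 2].mean())
    equilibrated = drift < 3.0 * max(se1 * math.sqrt(len(h1s) / 2), 1e-9)
    return SwellingResult(
        h1=float(h1), h2=float(h2), h1_se=float(se1), h2_se=float(se2),
        nu_cr=sys.nu_cr(), equilibrated=bool(equilibrated),
        heights_trace_h1=h1s, heights_trace_h2=h2s,
    )


def swelling_experiment(
    spec: NetworkSpec,
    collapse_steps: int = 8000,
    crosslink_steps: int = 1500,
    equil_steps: int = 4000,
    sample_chunks: int = 6,
    chunk_steps: int = 300,
    pre_stretch: float = 2.0,
) -> SwellingResult:
    """Cross-link a grafted matrix in the collapsed state, then measure swelling.

    Protocol: build above the LCST in a compact layer, equilibrate the
    collapsed film, cross-link to the target ``nu_cr``, sample the collapsed
    height ``h2``, switch below the LCST (with an affine pre-stretch to speed
    the slow swelling relaxation), equilibrate, sample the swollen height
    ``h1``.  The result carries the achieved ``nu_cr`` and an equilibration
    flag (drift of the swollen sampling window within 3 standard errors).
    """
    sys = build_grafted_matrix(spec)
    return _measure_swelling(
        sys, spec, collapse_steps, crosslink_steps, equil_steps,
        sample_chunks, chunk_steps, pre_stretch,
    )


def _cap_shell_points(R, h_cap, center_x, Ly, rng, density) -> np.ndarray:
    """Quasi-random points filling a spherical-cap shell (thickness 1) spanning y."""
    # sample within the cap bounding box, keep points within 1 of the sphere
    # surface and inside the cap
    c = math.sqrt(R * R - (R - h_cap) ** 2)
    zc = -(R - h_cap)  # sphere center below the substrate plane
    n_try = int(density * (2 * c) * Ly * h_cap * 4) + 50
    x = rng.uniform(center_x - c, center_x + c, n_try)
    y = rng.uniform(0, Ly, n_try)
    z = rng.uniform(0, h_cap, n_try)
    d = np.sqrt((x - center_x) ** 2 + (z - zc) ** 2)
    keep = (d <= R) & (d >= R - 1.0)
    return np.column_stack([x[keep], y[keep], z[keep]])


def build_cap_pinned_matrix(spec: CapPinSpec, net: NetworkSpec) -> DPDSystem:
    """Two frozen spherical-cap obstacles with a grafted, cap-pinned matrix between.

    The caps sit at opposite box sides (x = 0 and x = Lx/2 centers; periodic
    images make the domain array); the box x-length follows from the cap base
    width and ``separation``.  Matrix chains are grafted to the substrate
    strip between the caps at ``net.rho_g`` and pinned to cap-surface sites
    below ``pin_height`` at ``rho_pd``: after assembly each pin site binds its
    nearest matrix bead within the interaction range.
    """
    if spec.separation <= 0:
        raise ValueError("cap separation must be positive (caps may not overlap)")
    rng = np.random.default_rng(net.seed)
    c = spec.base_half_width()
    # two cap cells, each of width (base + separation)
    Lx = 2.0 * (2.0 * c + spec.separation)
    Ly, Lz = spec.box_y, spec.box_z
    box = (Lx, Ly, Lz)
    cap_centers = (0.0, Lx / 2.0)

    cap_pts = [
        _cap_shell_points(spec.R, spec.cap_height, cx, Ly, rng, net.rho_b)
        for cx in cap_centers
    ]
    # wrap the x=0 cap across the periodic boundary
    cap_pos = np.vstack(cap_pts)
    cap_pos[:, 0] %= Lx

    # grafted chains on the substrate strips between caps
    n_chains = int(round(net.rho_g * Lx * Ly))
    def on_substrate(x):
        for cx in cap_centers:
            dx = abs((x - cx + Lx / 2) % Lx - Lx / 2)
            if dx < c:
                return False
        return True
    chain_pos, bonds, anchor_idx, anchor_pos = [], [], [], []
    idx0 = 0
    # collapsed initial layer (see build_grafted_matrix)
    zcap = min(n_chains * net.n_beads / (net.rho_b * Lx * Ly) + 2.0, Lz - 1.0)
    placed = 0
    while placed < n_chains:
        x = rng.uniform(0, Lx)
        if not on_substrate(x):
            continue
        axy = (x, rng.uniform(0, Ly))
        chain_pos.append(_grow_chain(rng, axy, net.n_beads, Lx, Ly, Lz, zmax=zcap))
        for k in range(net.n_beads - 1):
            bonds.append((idx0 + k, idx0 + k + 1))
        anchor_idx.append(idx0)
        anchor_pos.append((axy[0] % Lx, axy[1] % Ly, 0.0))
        idx0 += net.n_beads
        placed += 1
    n_poly = idx0
    typ_poly = np.full(n_poly, PNIPAM)
    n_gma = int(round(net.gma_fraction * n_poly))
    typ_poly[rng.choice(n_poly, n_gma, replace=False)] = GMA

    n_solv = int(round(net.rho_b * Lx * Ly * Lz)) - n_poly - len(cap_pos)
    solv = rng.uniform(0, 1, (max(n_solv, 0), 3)) * np.array(box)
    walls = _wall_layers(Lx, Ly, Lz, net.rho_b, rng)

    sys = _assemble(
        [np.vstack(chain_pos) if chain_pos else np.empty((0, 3)), cap_pos, solv, walls],
        [typ_poly, np.full(len(cap_pos), PGMA), np.full(len(solv), WATER),
         np.full(len(walls), WALL)],
        [np.zeros(n_poly, bool), np.ones(len(cap_pos), bool),
         np.zeros(len(solv), bool), np.ones(len(walls), bool)],
        box, rng,
        bonds=np.array(bonds, np.int64).reshape(-1, 2),
        bond_kind=np.zeros(len(bonds), np.int64),
        anchor_idx=anchor_idx, anchor_pos=anchor_pos,
        max_extra_bonds=n_poly // 2 + 1 + n_poly,
        below_lcst=False, seed=net.seed,
    )
    sys.active[:n_poly] = typ_poly == GMA

    # pin sites on the cap surfaces below pin_height
    pin_sites = []
    for cx in cap_centers:
        zc = -(spec.R - spec.cap_height)
        area = 2.0 * spec.R * _cap_arc(spec.R, zc, spec.pin_height) * Ly / spec.R
        n_pins = int(round(spec.rho_pd * area))
        for _ in range(n_pins):
            # rejection-sample a surface point with z in [0, pin_height]
            for _try in range(200):
                theta = rng.uniform(0, 2 * math.pi)
                zs = rng.uniform(0.0, spec.pin_height)
                xr = math.sqrt(max(spec.R**2 - (zs - zc) ** 2, 0.0))
                xs = cx + xr * math.cos(theta)
                ys = rng.uniform(0, Ly)
                if abs(xs - cx) <= c:
                    pin_sites.append((xs % Lx, ys, zs))
                    break
    # each pin site binds its nearest matrix bead within r_c
    if pin_sites:
        from scipy.spatial import cKDTree

        matrix_idx = np.where(sys.matrix_mask())[0]
        pts = sys.pos[matrix_idx].copy()
        tree = cKDTree(pts, boxsize=[Lx, Ly, 1e9])
        extra_idx, extra_pos = [], []
        for s in pin_sites:
            d, k = tree.query([s[0], s[1], max(s[2], 0.0)])
            if d <= 1.5:
                extra_idx.append(matrix_idx[k])
                extra_pos.append(s)
        if extra_idx:
            sys.anchor_idx = np.concatenate([sys.anchor_idx, np.array(extra_idx, np.int64)])
            sys.anchor_pos = np.vstack([sys.anchor_pos, np.array(extra_pos)])
    sys._pin_count = len(pin_sites)
    return sys


def _cap_arc(R, zc, z_top):
    """Arc length of the cap cross-section from the substrate up to z_top."""
    th0 = math.asin(max(min(-zc / R, 1.0), -1.0))
    th1 = math.asin(max(min((z_top - zc) / R, 1.0), -1.0))
    return R * max(th1 - th0, 0.0)


def cap_swelling_experiment(
    spec: CapPinSpec,
    net: NetworkSpec,
    collapse_steps: int = 2500,
    crosslink_steps: int = 1200,
    equil_steps: int = 3000,
    sample_chunks: int = 5,
    chunk_steps: int = 250,
    pre_stretch: float = 2.0,
) -> SwellingResult:
    """Swelling ratio of the cap-pinned matrix (two-cap geometry).

    Same protocol as :func:`swelling_experiment` on the cap geometry.  The
    runs deliberately use a fixed late observation window; full network
    equilibration is not awaited and the result flags residual drift instead.
    """
    sys = build_cap_pinned_matrix(spec, net)
    return _measure_swelling(
        sys, net, collapse_steps, crosslink_steps, equil_steps,
        sample_chunks, chunk_steps, pre_stretch,
    )


def phase_separation_experiment(
    f: float,
    n_steps: int = 20000,
    box: tuple[float, float, float] = (16.0, 16.0, 12.0),
    n_beads: int = 20,
    graft_density: float = 0.6,
    seed: int = 0,
    min_cluster: int = 10,
):
    """Phase separation of mixed tethered PGMA/PNIPAM chains in a theta solvent.

    A fraction ``f`` of the grafted chains is PGMA (equal chain lengths, so
    ``f`` is also the PGMA mass fraction); PGMA and PNIPAM repel strongly
    while both sit near theta conditions with the solvent.  After ``n_steps``
    the PGMA beads are clustered by distance (cutoff ``r_c``) and each
    cluster is sliced horizontally and fitted with the spherical-cap relation.

    Returns ``(system, cap_fits, clusters)`` where ``cap_fits`` is a list of
    :class:`~thermosort.capgeom.SphericalCap` per retained domain with the
    per-slice fit, and ``clusters`` the list of PGMA bead-index arrays.
    """
    if not (0.0 < f < 1.0):
        raise ValueError("mass fraction f must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    Lx, Ly, Lz = box
    n_chains = int(round(graft_density * Lx * Ly))
    n_pgma = int(round(f * n_chains))
    chain_pos, bonds, anchor_idx, anchor_pos, typ_list = [], [], [], [], []
    idx0 = 0
    for ci in range(n_chains):
        axy = (rng.uniform(0, Lx), rng.uniform(0, Ly))
        chain_pos.append(_grow_chain(rng, axy, n_beads, Lx, Ly, Lz, zmax=0.6 * Lz))
        for k in range(n_beads - 1):
            bonds.append((idx0 + k, idx0 + k + 1))
        anchor_idx.append(idx0)
        anchor_pos.append((axy[0] % Lx, axy[1] % Ly, 0.0))
        typ_list.append(np.full(n_beads, PGMA if ci < n_pgma else PNIPAM))
        idx0 += n_beads
    n_poly = idx0
    typ_poly = np.concatenate(typ_list)
    n_solv = int(round(3.0 * Lx * Ly * Lz)) - n_poly
    solv = rng.uniform(0, 1, (max(n_solv, 0), 3)) * np.array(box)
    walls = _wall_layers(Lx, Ly, Lz, 3.0, rng)
    sys = _assemble(
        [np.vstack(chain_pos), solv, walls],
        [typ_poly, np.full(len(solv), WATER), np.full(len(walls), WALL)],
        [np.zeros(n_poly, bool), np.zeros(len(solv), bool), np.ones(len(walls), bool)],
        box, rng,
        bonds=np.array(bonds, np.int64), bond_kind=np.zeros(len(bonds), np.int64),
        anchor_idx=anchor_idx, anchor_pos=anchor_pos,
        seed=seed,
    )
    # theta-like solvent for both polymers during phase separation
    for p in (PNIPAM, GMA):
        sys.a_matrix[p, WATER] = sys.a_matrix[WATER, p] = _A_THETA
    integrate(sys, n_steps)

    # distance-based clustering of PGMA beads
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial import cKDTree

    pg = np.where((sys.types == PGMA) & (~sys.frozen))[0]
    clusters = []
    fits = []
    if len(pg):
        pts = sys.pos[pg].copy()
        pts[:, 2] += 10.0  # keep boxsize positive in z for the tree
        tree = cKDTree(np.column_stack([pts[:, 0] % Lx, pts[:, 1] % Ly, pts[:, 2]]),
                       boxsize=[Lx, Ly, 1e9])
        pairs = tree.query_pairs(1.0, output_type="ndarray")
        n = len(pg)
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        ncomp, labels = connected_components(adj, directed=False)
        for c in range(ncomp):
            members = pg[labels == c]
            if len(members) < min_cluster:
                continue
            clusters.append(members)
            cap = _fit_cluster_cap(sys.pos[members], Lx, Ly)
            if cap is not None:
                fits.append(cap)
    return sys, fits, clusters


def _fit_cluster_cap(pts: np.ndarray, Lx: float, Ly: float) -> SphericalCap | None:
    """Slice a bead cluster horizontally and fit the spherical-cap relation.

    Per slab of thickness 1 the occupied cross-section area is estimated from
    the 2-D convex hull of the slab's beads (plus a half-bead margin), giving
    an equivalent-disc radius per height; R_sp follows by least squares.
    """
    from scipy.spatial import ConvexHull, QhullError

    # unwrap laterally around the cluster's circular mean
    xy = pts[:, :2].copy()
    for d, L in ((0, Lx), (1, Ly)):
        ang = xy[:, d] / L * 2 * np.pi
        mean = math.atan2(np.sin(ang).mean(), np.cos(ang).mean())
        xy[:, d] = (ang - mean + np.pi) % (2 * np.pi) - np.pi
        xy[:, d] = xy[:, d] * L / (2 * np.pi)
    z = pts[:, 2]
    H = float(z.max())
    h_rel, rads = [], []
    for z0 in np.arange(0.0, H, 1.0):
        sel = (z >= z0) & (z < z0 + 1.0)
        if np.sum(sel) < 4:
            continue
        try:
            hull = ConvexHull(xy[sel])
            area = hull.volume  # 2-D hull: volume is the area
        except QhullError:
            continue
        r_eq = math.sqrt(area / math.pi) + 0.5
        h_rel.append(H - (z0 + 0.5))
        rads.append(r_eq)
    if len(h_rel) < 2:
        return None
    h_rel = np.asarray(h_rel)
    rads = np.asarray(rads)
    x = 2.0 * h_rel
    y = rads**2 + h_rel**2
    denom = float(np.dot(x, x))
    if denom <= 0:
        return None
    rsp = float(np.dot(x, y) / denom)
    if not np.isfinite(rsp) or rsp <= H / 2:
        return None
    cx = float(np.mean(pts[:, 0]))
    cy = float(np.mean(pts[:, 1]))
    return SphericalCap(R_sp=rsp, H=H, center_xy=(cx, cy))
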