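"""Metropolis Monte Carlo model of two cell types sorting on a microstructured surface.

The surface is an array of fixed, non-overlapping cylindrical adhesive domains
(diameter ``D_d``, height ``H_d = D_d``) at coverage ``sigma_d``, embedded in a
thermoresponsive polymer phase.  Cells are hard spheres of diameter ``D`` that
deform on contact into a flat circular facet; the adhesion energy is linear in
the cell-domain contact area (per-type prefactor ``A_kd < 0``), and when the
polymer is swollen its surface at ``H_d + h_p`` repels the cell with energy
``B_p`` per unit area of the sphere's cross-section at the polymer level,
excluding the regions occupied by the domain tops.  Gravity pulls cells toward
the surface with energy ``g_w * z``.  Cell motion is nonthermal noise (flow,
vibration) modelled as Metropolis dynamics at an effective temperature
``T_eff``, which sets the energy unit.

A sorting run has two stages: adsorption (collapsed polymer, ``B_p = 0``) until
the potential energy saturates and all cells sit on the domains, then
desorption at a chosen ``B_p`` with a swollen polymer.  The observables are the
per-type fractions of cells remaining attached (center within ``r_cut = D/2``
of the domain-top plane) and the separation factor, the attached type-1/type-2
ratio relative to the initial 1:1 loading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "MicroSurface",
    "CellEnsemble",
    "MCParams",
    "StageResult",
    "SweepResult",
    "place_domains_rsa",
    "contact_area",
    "repulsion_area",
    "total_energy",
    "accept_move",
    "mc_step",
    "run_adsorption",
    "run_desorption",
    "separation_factor_sim",
    "sweep",
]

_COVERAGE_TOL = 0.005


# --------------------------------------------------------------------------- #
# data containers
# --------------------------------------------------------------------------- #


@dataclass
class MicroSurface:
    """Fixed array of cylindrical adhesive domains plus a polymer phase.

    ``centers`` holds lateral domain centers on the periodic ``L x L`` substrate;
    domain height equals the diameter (``H_d = D_d``).  ``swollen`` selects the
    polymer state: collapsed polymer exerts no force, swollen polymer presents a
    repulsive surface at ``H_d + h_p`` with strength ``B_p`` per unit area.
    """

    L: float
    D_d: float
    sigma_d: float
    centers: np.ndarray
    swollen: bool = False
    h_p: float = 0.5
    B_p: float = 0.0

    @property
    def H_d(self) -> float:
        return self.D_d

    @property
    def coverage(self) -> float:
        return len(self.centers) * math.pi * (self.D_d / 2.0) ** 2 / self.L**2


@dataclass
class CellEnsemble:
    """Hard-sphere cells of two types with per-type adhesion strengths.

    ``A_kd < 0`` makes domain contact attractive; type 1 binds more strongly
    than type 2 (|A_1d| > |A_2d|).
    """

    positions: np.ndarray  # (N, 3)
    types: np.ndarray  # (N,), values 1 or 2
    D: float = 10.0
    A_1d: float = -0.4
    A_2d: float = -0.3

    @property
    def N(self) -> int:
        return len(self.types)

    def counts(self) -> tuple[int, int]:
        return int(np.sum(self.types == 1)), int(np.sum(self.types == 2))


@dataclass
class MCParams:
    """Monte Carlo protocol parameters (energies in units of ``T_eff``).

    The defaults are the documented calibration that reproduces the simulated
    sorting working points (the polymer rise ``h_p``, deformation limit
    ``delta_max``, gravity ``g_w`` and move size ``max_disp`` are not fixed by
    the model definition and were calibrated once, together, against the
    desorption working points; see docs/methods.md).
    """

    T_eff: float = 1.0
    g_w: float = 0.14
    max_disp: float = 1.0
    delta_max: float = 3.0
    h_p: float = 0.5
    box_height: float = 60.0
    adsorption_steps: int = 600_000
    desorption_steps: int = 1_200_000
    sample_every: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T_eff <= 0:
            raise ValueError("T_eff must be positive")
        if not (0 < self.delta_max < 5.0):
            raise ValueError("delta_max must lie in (0, D/2)")

    def r_cut(self, D: float) -> float:
        """Attachment cutoff, measured from the domain-top plane."""
        return D / 2.0


@dataclass
class StageResult:
    """Outcome of one MC stage."""

    frac1: float
    frac2: float
    frac1_se: float
    frac2_se: float
    acceptance: float
    energy_trace: np.ndarray
    trace_every: int
    saturation_step: int | None
    z_profile: np.ndarray
    z_edges: np.ndarray

    @property
    def separation_factor(self) -> float | None:
        sf, defined = separation_factor_sim(self.frac1, self.frac2, 1.0)
        return sf if defined else None


@dataclass
class SweepResult:
    """Full factorial (D_d, B_p) sweep output."""

    D_d: np.ndarray
    B_p: np.ndarray
    frac1: np.ndarray  # (n_Dd, n_Bp) percent
    frac2: np.ndarray
    frac1_se: np.ndarray
    frac2_se: np.ndarray
    sf: np.ndarray
    sf_defined: np.ndarray

    def peak(self, d_index: int) -> tuple[float, float]:
        """(B_p at the separation-factor maximum, peak SF) for one domain size."""
        curve = np.where(self.sf_defined[d_index], self.sf[d_index], -np.inf)
        j = int(np.argmax(curve))
        return float(self.B_p[j]), float(self.sf[d_index, j])


# --------------------------------------------------------------------------- #
# numba kernels
# --------------------------------------------------------------------------- #


@njit(cache=True)
def _lens_area(r1, r2, d):
    """Intersection area of two discs with radii r1, r2 at center distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        rm = r1 if r1 < r2 else r2
        return math.pi * rm * rm
    d2 = d * d
    a1 = r1 * r1
    a2 = r2 * r2
    alpha = math.acos((d2 + a1 - a2) / (2.0 * d * r1))
    beta = math.acos((d2 + a2 - a1) / (2.0 * d * r2))
    tri = 0.5 * math.sqrt(
        max((-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2), 0.0)
    )
    return a1 * alpha + a2 * beta - tri


@njit(cache=True)
def _rsa_disks(L, radius, n_target, max_attempts, seed):
    """RSA of n_target non-overlapping disks on a periodic L x L substrate."""
    np.random.seed(seed)
    ncell = max(int(L / (2.0 * radius)), 1)
    if ncell < 3:
        ncell = 1
    cell = L / ncell
    head = -np.ones(ncell * ncell, dtype=np.int64)
    nxt = -np.ones(n_target, dtype=np.int64)
    xs = np.empty(n_target)
    ys = np.empty(n_target)
    rr = 4.0 * radius * radius
    placed = 0
    attempts = 0
    while placed < n_target and attempts < max_attempts:
        attempts += 1
        x = np.random.random() * L
        y = np.random.random() * L
        ci = int(x / cell)
        cj = int(y / cell)
        ok = True
        for di in range(-1, 2):
            for dj in range(-1, 2):
                ii = (ci + di) % ncell
                jj = (cj + dj) % ncell
                k = head[ii * ncell + jj]
                while k >= 0:
                    dx = xs[k] - x
                    dy = ys[k] - y
                    if dx > 0.5 * L:
                        dx -= L
                    elif dx < -0.5 * L:
                        dx += L
                    if dy > 0.5 * L:
                        dy -= L
                    elif dy < -0.5 * L:
                        dy += L
                    if dx * dx + dy * dy < rr:
                        ok = False
                        break
                    k = nxt[k]
                if not ok:
                    break
            if not ok:
                break
        if ok:
            xs[placed] = x
            ys[placed] = y
            idx = ci * ncell + cj
            nxt[placed] = head[idx]
            head[idx] = placed
            placed += 1
    return placed, xs[:placed], ys[:placed]


@njit(cache=True)
def _surface_areas(
    x, y, u, D, rd, swollen, h_p, gx, gy, gstart, gidx, ncell, gcell, L
):
    """(contact_area, repulsion_area) for a cell center at lateral (x, y), height
    u above the domain-top plane.  Domain centers are held in a CSR uniform grid."""
    half = 0.5 * D
    contact = 0.0
    rep = 0.0
    a = 0.0
    if u < half:
        a = math.sqrt(half * half - u * u)
    b = -1.0
    if swollen:
        dpl = u - h_p
        if dpl < half:
            if dpl <= 0.0:
                b = half
            else:
                b = math.sqrt(half * half - dpl * dpl)
    if a <= 0.0 and b <= 0.0:
        return 0.0, 0.0
    rmax = (a if a > b else b) + rd
    ci = int(x / gcell)
    cj = int(y / gcell)
    span = int(rmax / gcell) + 1
    rep_excl = 0.0
    for di in range(-span, span + 1):
        ii = (ci + di) % ncell
        for dj in range(-span, span + 1):
            jj = (cj + dj) % ncell
            s = gstart[ii * ncell + jj]
            e = gstart[ii * ncell + jj + 1]
            for kk in range(s, e):
                k = gidx[kk]
                dx = gx[k] - x
                dy = gy[k] - y
                if dx > 0.5 * L:
                    dx -= L
                elif dx < -0.5 * L:
                    dx += L
                if dy > 0.5 * L:
                    dy -= L
                elif dy < -0.5 * L:
                    dy += L
                d = math.sqrt(dx * dx + dy * dy)
                if a > 0.0 and d < a + rd:
                    contact += _lens_area(a, rd, d)
                if b > 0.0 and d < b + rd:
                    rep_excl += _lens_area(b, rd, d)
    if b > 0.0:
        rep = math.pi * b * b - rep_excl
        if rep < 0.0:
            rep = 0.0
    return contact, rep


@njit(cache=True)
def _cell_energy(
    x, y, z, A_k, B_p, g_w, H_d, D, rd, swollen, h_p,
    gx, gy, gstart, gidx, ncell, gcell, L,
):
    u = z - H_d
    contact, rep = _surface_areas(
        x, y, u, D, rd, swollen, h_p, gx, gy, gstart, gidx, ncell, gcell, L
    )
    return A_k * contact + B_p * rep + g_w * z


@njit(cache=True)
def _run_stage_kernel(
    pos, types, D, A1, A2, B_p, swollen, h_p, delta_max, g_w, T, step_disp,
    L, Lz, H_d, rd,
    gx, gy, gstart, gidx, ncell, gcell,
    n_steps, sample_every, trace_every, seed, r_cut,
    z_samples_max,
):
    """Metropolis stage: returns attachment stats, energy trace, z-profile,
    acceptance rate and optional raw z samples from the second half."""
    np.random.seed(seed)
    N = pos.shape[0]
    half_d = 0.5 * D
    u_min = half_d - delta_max
    z_min = H_d + u_min
    D2 = D * D

    # initial per-cell surface energies and total
    e_cell = np.empty(N)
    for i in range(N):
        A_k = A1 if types[i] == 1 else A2
        e_cell[i] = _cell_energy(
            pos[i, 0], pos[i, 1], pos[i, 2], A_k, B_p, g_w, H_d, D, rd,
            swollen, h_p, gx, gy, gstart, gidx, ncell, gcell, L,
        )
    e_tot = e_cell.sum()

    n_trace = n_steps // trace_every + 1
    trace = np.empty(n_trace)
    trace_n = 0

    nbins = int(Lz / 0.5) + 1
    prof = np.zeros(nbins)
    att1 = 0.0
    att2 = 0.0
    att1_sq = 0.0
    att2_sq = 0.0
    n_samp = 0
    z_samples = np.empty(z_samples_max)
    n_z = 0
    n_acc = 0
    half_steps = n_steps // 2

    for step in range(n_steps):
        if step % trace_every == 0:
            trace[trace_n] = e_tot
            trace_n += 1
        i = np.random.randint(0, N)
        xo = pos[i, 0]
        yo = pos[i, 1]
        zo = pos[i, 2]
        xn = xo + (2.0 * np.random.random() - 1.0) * step_disp
        yn = yo + (2.0 * np.random.random() - 1.0) * step_disp
        zn = zo + (2.0 * np.random.random() - 1.0) * step_disp
        if xn >= L:
            xn -= L
        elif xn < 0.0:
            xn += L
        if yn >= L:
            yn -= L
        elif yn < 0.0:
            yn += L
        ok = True
        if zn < z_min or zn > Lz - half_d:
            ok = False  # hard wall below, reflecting ceiling above
        if ok:
            for j in range(N):
                if j == i:
                    continue
                dx = pos[j, 0] - xn
                dy = pos[j, 1] - yn
                dz = pos[j, 2] - zn
                if dx > 0.5 * L:
                    dx -= L
                elif dx < -0.5 * L:
                    dx += L
                if dy > 0.5 * L:
                    dy -= L
                elif dy < -0.5 * L:
                    dy += L
                if dx * dx + dy * dy + dz * dz < D2:
                    ok = False
                    break
        if ok:
            A_k = A1 if types[i] == 1 else A2
            e_new = _cell_energy(
                xn, yn, zn, A_k, B_p, g_w, H_d, D, rd, swollen, h_p,
                gx, gy, gstart, gidx, ncell, gcell, L,
            )
            dE = e_new - e_cell[i]
            if dE <= 0.0 or np.random.random() < math.exp(-dE / T):
                pos[i, 0] = xn
                pos[i, 1] = yn
                pos[i, 2] = zn
                e_tot += dE
                e_cell[i] = e_new
                n_acc += 1

        if step >= half_steps and step % sample_every == 0:
            c1 = 0
            c2 = 0
            for j in range(N):
                zb = int(pos[j, 2] / 0.5)
                if zb < nbins:
                    prof[zb] += 1.0
                if pos[j, 2] - H_d <= r_cut:
                    if types[j] == 1:
                        c1 += 1
                    else:
                        c2 += 1
                if n_z < z_samples_max:
                    z_samples[n_z] = pos[j, 2]
                    n_z += 1
            att1 += c1
            att2 += c2
            att1_sq += c1 * c1
            att2_sq += c2 * c2
            n_samp += 1

    return (
        trace[:trace_n], att1, att2, att1_sq, att2_sq, n_samp,
        prof, n_acc, z_samples[:n_z],
    )


# --------------------------------------------------------------------------- #
# public API
# --------------------------------------------------------------------------- #


def place_domains_rsa(
    L: float, D_d: float, sigma_d: float, seed: int, attempt_factor: int = 5000
) -> MicroSurface:
    """Place non-overlapping domains by random sequential adsorption.

    The domain count is ``round(sigma_d * L^2 / (pi (D_d/2)^2))``; placements
    are uniform with periodic wrapping and redrawn on overlap, with an attempt
    budget of ``attempt_factor * n``.  ``sigma_d`` must stay below the disc RSA
    jamming coverage (~0.547) or placement cannot terminate.
    """
    if sigma_d < 0:
        raise ValueError("sigma_d must be >= 0")
    if sigma_d >= 0.52:
        raise ValueError(f"sigma_d={sigma_d} too close to the RSA jamming coverage")
    r = D_d / 2.0
    n = int(round(sigma_d * L * L / (math.pi * r * r))) if sigma_d > 0 else 0
    if n == 0:
        centers = np.empty((0, 2))
    else:
        placed, xs, ys = _rsa_disks(L, r, n, attempt_factor * n, seed)
        if placed < n:
            raise RuntimeError(
                f"domain placement failed: {placed}/{n} after {attempt_factor * n} attempts"
            )
        centers = np.column_stack([xs, ys])
    surf = MicroSurface(L=L, D_d=D_d, sigma_d=sigma_d, centers=centers)
    if n > 0 and abs(surf.coverage - sigma_d) > _COVERAGE_TOL:
        raise RuntimeError(
            f"achieved coverage {surf.coverage:.4f} misses target {sigma_d} "
            f"beyond tolerance {_COVERAGE_TOL}"
        )
    return surf


def _domain_grid(surface: MicroSurface, D: float):
    """CSR uniform grid over domain centers for neighbour queries.

    The grid cell is at least ``D/2 + r_d`` so a span-1 scan covers any facet
    or cross-section disc; smaller cells with a wider scan are used for large
    search radii (handled by the kernel's span computation).
    """
    rd = surface.D_d / 2.0
    target = max(D / 2.0 + rd, 1.0)
    ncell = max(int(surface.L / target), 1)
    gcell = surface.L / ncell
    if len(surface.centers) == 0:
        gstart = np.zeros(ncell * ncell + 1, dtype=np.int64)
        gidx = np.empty(0, dtype=np.int64)
        return (
            np.empty(0), np.empty(0), gstart, gidx, ncell, gcell,
        )
    gx = surface.centers[:, 0].copy()
    gy = surface.centers[:, 1].copy()
    ci = (gx / gcell).astype(np.int64) % ncell
    cj = (gy / gcell).astype(np.int64) % ncell
    flat = ci * ncell + cj
    order = np.argsort(flat, kind="stable")
    gidx = order.astype(np.int64)
    counts = np.bincount(flat, minlength=ncell * ncell)
    gstart = np.zeros(ncell * ncell + 1, dtype=np.int64)
    np.cumsum(counts, out=gstart[1:])
    return gx, gy, gstart, gidx, ncell, gcell


def contact_area(
    position: np.ndarray, surface: MicroSurface, D: float, delta_max: float
) -> float:
    """Total cell-domain contact area of the deformation facet.

    The facet is the flat circular section of the sphere at the domain-top
    plane, radius ``sqrt((D/2)^2 - u^2)`` for center height ``u`` above that
    plane; the contact area is the sum of facet/domain-top disc intersections.
    Raises if the center is below the deformation limit (hard wall).
    """
    x, y, z = position
    u = z - surface.H_d
    if u < D / 2.0 - delta_max:
        raise ValueError(f"hard-wall violation: u={u} < D/2 - delta_max")
    gx, gy, gstart, gidx, ncell, gcell = _domain_grid(surface, D)
    c, _ = _surface_areas(
        x, y, u, D, surface.D_d / 2.0, False, 0.0,
        gx, gy, gstart, gidx, ncell, gcell, surface.L,
    )
    return float(c)


def repulsion_area(position: np.ndarray, surface: MicroSurface, D: float) -> float:
    """Cross-section area of the cell sphere at the swollen polymer surface,
    excluding the parts over domain tops.

    The polymer surface sits at ``H_d + h_p``.  If the plane passes below the
    sphere's equator the disc radius is clamped at ``D/2``.  Collapsed polymer
    is a state error: it exerts no force and has no defined surface.
    """
    if not surface.swollen:
        raise RuntimeError("repulsion_area requires the swollen polymer state")
    x, y, z = position
    u = z - surface.H_d
    gx, gy, gstart, gidx, ncell, gcell = _domain_grid(surface, D)
    _, rep = _surface_areas(
        x, y, u, D, surface.D_d / 2.0, True, surface.h_p,
        gx, gy, gstart, gidx, ncell, gcell, surface.L,
    )
    return float(rep)


def total_energy(
    position: np.ndarray,
    cell_type: int,
    surface: MicroSurface,
    cells: CellEnsemble,
    params: MCParams,
) -> float:
    """Single-cell energy: adhesion + polymer repulsion + gravity.

    ``E = A_kd * contact_area + B_p * repulsion_area + g_w * z``.
    Hard-wall violations raise; hard-sphere overlaps are the caller's concern
    (the MC kernel rejects them as infinite-energy moves).
    """
    x, y, z = position
    u = z - surface.H_d
    if u < cells.D / 2.0 - params.delta_max:
        raise ValueError("hard-wall violation")
    A_k = cells.A_1d if cell_type == 1 else cells.A_2d
    gx, gy, gstart, gidx, ncell, gcell = _domain_grid(surface, cells.D)
    return float(
        _cell_energy(
            x, y, z, A_k, surface.B_p, params.g_w, surface.H_d, cells.D,
            surface.D_d / 2.0, surface.swollen, surface.h_p,
            gx, gy, gstart, gidx, ncell, gcell, surface.L,
        )
    )


def accept_move(delta_E: float, T_eff: float, rng: np.random.Generator) -> bool:
    """Metropolis acceptance: always for downhill moves, else with exp(-dE/T)."""
    if delta_E <= 0.0:
        return True
    return rng.random() < math.exp(-delta_E / T_eff)


def mc_step(
    surface: MicroSurface,
    cells: CellEnsemble,
    params: MCParams,
    rng: np.random.Generator,
) -> bool:
    """One attempted single-cell move (reference implementation).

    Picks a cell uniformly, proposes a uniform displacement in a cube of
    half-width ``max_disp``, wraps laterally, rejects hard-constraint
    violations, and applies the Metropolis rule.  Returns acceptance.  The
    production stages use the compiled kernel, which implements the same move.
    """
    N = cells.N
    i = int(rng.integers(N))
    old = cells.positions[i].copy()
    new = old + (2.0 * rng.random(3) - 1.0) * params.max_disp
    new[0] %= surface.L
    new[1] %= surface.L
    z_min = surface.H_d + cells.D / 2.0 - params.delta_max
    if new[2] < z_min or new[2] > params.box_height - cells.D / 2.0:
        return False
    delta = cells.positions - new
    delta[:, :2] -= np.round(delta[:, :2] / surface.L) * surface.L
    d2 = np.einsum("ij,ij->i", delta, delta)
    d2[i] = np.inf
    if np.any(d2 < cells.D**2):
        return False
    t = int(cells.types[i])
    e_old = total_energy(old, t, surface, cells, params)
    e_new = total_energy(new, t, surface, cells, params)
    if accept_move(e_new - e_old, params.T_eff, rng):
        cells.positions[i] = new
        return True
    return False


def initialize_cells(
    surface: MicroSurface,
    params: MCParams,
    N1: int = 100,
    N2: int = 100,
    D: float = 10.0,
    A_1d: float = -0.4,
    A_2d: float = -0.3,
    z_max: float | None = None,
) -> CellEnsemble:
    """Random non-overlapping initial cell configuration suspended in the box."""
    rng = np.random.default_rng(params.seed + 7919)
    N = N1 + N2
    z_lo = surface.H_d + D / 2.0
    z_hi = z_max if z_max is not None else min(params.box_height - D / 2.0, z_lo + 30.0)
    pos = np.empty((N, 3))
    placed = 0
    budget = 100_000
    while placed < N and budget > 0:
        budget -= 1
        cand = np.array(
            [
                rng.uniform(0, surface.L),
                rng.uniform(0, surface.L),
                rng.uniform(z_lo, z_hi),
            ]
        )
        if placed:
            delta = pos[:placed] - cand
            delta[:, :2] -= np.round(delta[:, :2] / surface.L) * surface.L
            if np.min(np.einsum("ij,ij->i", delta, delta)) < D * D:
                continue
        pos[placed] = cand
        placed += 1
    if placed < N:
        raise RuntimeError("could not place initial cells without overlap")
    types = np.concatenate([np.ones(N1, dtype=np.int64), np.full(N2, 2, dtype=np.int64)])
    rng.shuffle(types)
    return CellEnsemble(positions=pos, types=types, D=D, A_1d=A_1d, A_2d=A_2d)


def _saturation_step(trace: np.ndarray, trace_every: int, tol_frac: float = 0.05) -> int | None:
    """First trace step whose energy stays within a band around the final mean."""
    if len(trace) < 8:
        return None
    tail = trace[int(0.75 * len(trace)):]
    level = tail.mean()
    band = max(tol_frac * abs(level), 3.0 * tail.std() + 1e-12)
    inside = np.abs(trace - level) <= band
    # last crossing into the band
    idx = np.where(~inside)[0]
    first = 0 if len(idx) == 0 else int(idx[-1]) + 1
    if first >= len(trace):
        return None
    return first * trace_every


def _run_stage(
    surface: MicroSurface,
    cells: CellEnsemble,
    params: MCParams,
    n_steps: int,
    seed: int,
    collect_z: int = 0,
) -> StageResult:
    gx, gy, gstart, gidx, ncell, gcell = _domain_grid(surface, cells.D)
    trace_every = max(n_steps // 200, 1)
    (
        trace, att1, att2, att1_sq, att2_sq, n_samp, prof, n_acc, z_samples,
    ) = _run_stage_kernel(
        cells.positions, cells.types, cells.D, cells.A_1d, cells.A_2d,
        surface.B_p, surface.swollen, surface.h_p, params.delta_max,
        params.g_w, params.T_eff, params.max_disp,
        surface.L, params.box_height, surface.H_d, surface.D_d / 2.0,
        gx, gy, gstart, gidx, ncell, gcell,
        n_steps, params.sample_every, trace_every, seed,
        params.r_cut(cells.D), collect_z,
    )
    n1, n2 = cells.counts()
    if n_samp > 0:
        m1, m2 = att1 / n_samp, att2 / n_samp
        v1 = max(att1_sq / n_samp - m1 * m1, 0.0)
        v2 = max(att2_sq / n_samp - m2 * m2, 0.0)
        # correlated samples: conservative effective sample count
        neff = max(n_samp / 10.0, 1.0)
        se1 = math.sqrt(v1 / neff) / max(n1, 1) * 100.0
        se2 = math.sqrt(v2 / neff) / max(n2, 1) * 100.0
        f1 = 100.0 * m1 / max(n1, 1)
        f2 = 100.0 * m2 / max(n2, 1)
    else:
        f1 = f2 = se1 = se2 = float("nan")
    edges = np.arange(len(prof) + 1) * 0.5
    res = StageResult(
        frac1=f1,
        frac2=f2,
        frac1_se=se1,
        frac2_se=se2,
        acceptance=n_acc / n_steps,
        energy_trace=trace,
        trace_every=trace_every,
        saturation_step=_saturation_step(trace, trace_every),
        z_profile=prof,
        z_edges=edges,
    )
    res.z_samples = z_samples  # raw heights, second half of the stage
    return res


def run_adsorption(
    surface: MicroSurface, cells: CellEnsemble, params: MCParams, collect_z: int = 0
) -> StageResult:
    """Adsorption stage: collapsed polymer, ``B_p = 0``; cells settle on domains.

    Monitors the potential energy and reports the saturation step; with the
    standard loading the stage ends with all cells attached.
    """
    surface.swollen = False
    surface.B_p = 0.0
    return _run_stage(
        surface, cells, params, params.adsorption_steps, params.seed, collect_z
    )


def run_desorption(
    surface: MicroSurface,
    cells: CellEnsemble,
    params: MCParams,
    B_p: float,
    collect_z: int = 0,
) -> StageResult:
    """Desorption stage: swollen polymer at repulsion strength ``B_p``.

    Starts from the adsorbed configuration; attached counts and the density
    profile are averaged over the final half of the stage.
    """
    if B_p < 0:
        raise ValueError("B_p must be >= 0")
    surface.swollen = True
    surface.B_p = B_p
    surface.h_p = params.h_p
    return _run_stage(
        surface, cells, params, params.desorption_steps, params.seed + 1, collect_z
    )


def separation_factor_sim(
    attached_1: float, attached_2: float, initial_ratio: float = 1.0
) -> tuple[float, bool]:
    """Separation factor of a simulated run and whether it is defined.

    ``SF = (attached_1 / attached_2) / initial_ratio``; undefined (flagged
    False) when no type-2 cells remain attached.
    """
    if attached_1 < 0 or attached_2 < 0:
        raise ValueError("attached counts must be >= 0")
    if attached_2 == 0:
        return float("nan"), False
    return (attached_1 / attached_2) / initial_ratio, True


def two_stage_run(
    D_d: float,
    B_p: float,
    params: MCParams,
    L: float = 240.0,
    sigma_d: float = 0.48,
    N1: int = 100,
    N2: int = 100,
    D: float = 10.0,
    A_1d: float = -0.4,
    A_2d: float = -0.3,
    cells: CellEnsemble | None = None,
    surface: MicroSurface | None = None,
) -> tuple[StageResult, StageResult, MicroSurface, CellEnsemble]:
    """Full adsorption + desorption protocol at one working point.

    Pass a pre-adsorbed (surface, cells) pair to reuse the adsorption stage
    across a ``B_p`` grid, mirroring the protocol in which every desorption run
    starts from the final adsorbed configuration.
    """
    if surface is None:
        surface = place_domains_rsa(L, D_d, sigma_d, params.seed + 13)
    if cells is None:
        cells = initialize_cells(
            surface, params, N1=N1, N2=N2, D=D, A_1d=A_1d, A_2d=A_2d
        )
        ads = run_adsorption(surface, cells, params)
    else:
        ads = None
    work = CellEnsemble(
        positions=cells.positions.copy(),
        types=cells.types,
        D=cells.D,
        A_1d=cells.A_1d,
        A_2d=cells.A_2d,
    )
    des = run_desorption(surface, work, params, B_p)
    return ads, des, surface, cells


def sweep(
    params: MCParams,
    D_d_list,
    B_p_grid,
    n_seeds: int = 3,
    L: float = 240.0,
    sigma_d: float = 0.48,
    N1: int = 100,
    N2: int = 100,
    D: float = 10.0,
    A_1d: float = -0.4,
    A_2d: float = -0.3,
    progress: bool = False,
) -> SweepResult:
    """Full factorial (D_d, B_p) sweep, seed-averaged.

    Per (D_d, seed): one surface and one adsorption stage; every ``B_p`` run
    restarts desorption from that adsorbed configuration with an independent
    seed.  Fractions are percent of the initial per-type loading; the SF
    matrix carries NaN with ``sf_defined = False`` where type 2 fully detached.
    """
    D_d_list = np.asarray(list(D_d_list), dtype=float)
    B_p_grid = np.asarray(list(B_p_grid), dtype=float)
    if len(D_d_list) == 0 or len(B_p_grid) == 0:
        raise ValueError("D_d and B_p grids must be non-empty")
    shape = (len(D_d_list), len(B_p_grid))
    f1 = np.zeros(shape)
    f2 = np.zeros(shape)
    v1 = np.zeros(shape)
    v2 = np.zeros(shape)
    for a, D_d in enumerate(D_d_list):
        for s in range(n_seeds):
            p = replace(params, seed=params.seed + 1000 * s + int(1e6 * D_d))
            surface = place_domains_rsa(L, D_d, sigma_d, p.seed + 13)
            cells = initialize_cells(surface, p, N1=N1, N2=N2, D=D, A_1d=A_1d, A_2d=A_2d)
            run_adsorption(surface, cells, p)
            base = cells.positions.copy()
            for b, B_p in enumerate(B_p_grid):
                pb = replace(p, seed=p.seed + 17 * b)
                work = CellEnsemble(
                    positions=base.copy(), types=cells.types, D=D, A_1d=A_1d, A_2d=A_2d
                )
                res = run_desorption(surface, work, pb, float(B_p))
                f1[a, b] += res.frac1
                f2[a, b] += res.frac2
                v1[a, b] += res.frac1**2
                v2[a, b] += res.frac2**2
                if progress:
                    print(
                        f"D_d={D_d:.2f} seed={s} B_p={B_p:.3f} "
                        f"f1={res.frac1:.1f}% f2={res.frac2:.1f}%"
                    )
    f1 /= n_seeds
    f2 /= n_seeds
    se1 = np.sqrt(np.maximum(v1 / n_seeds - f1**2, 0.0) / max(n_seeds - 1, 1))
    se2 = np.sqrt(np.maximum(v2 / n_seeds - f2**2, 0.0) / max(n_seeds - 1, 1))
    sf = np.full(shape, np.nan)
    # the factor is only measurable while at least ~1 type-2 cell remains
    # attached on average; below that the ratio is shot-noise dominated
    defined = f2 * N2 / 100.0 >= 1.0
    sf[defined] = f1[defined] / f2[defined]
    return SweepResult(
        D_d=D_d_list, B_p=B_p_grid, frac1=f1, frac2=f2,
        frac1_se=se1, frac2_se=se2, sf=sf, sf_defined=defined,
    )
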