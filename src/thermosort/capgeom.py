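"""Spherical-cap geometry of adhesive microdomains and derived surface statistics.

Phase-separated PGMA domains on a microstructured thermoresponsive surface are
well approximated by spherical caps: a cap of height ``H`` cut from a sphere of
radius ``R_sp``, sitting on a basal plane, partially buried in the surrounding
PNIPAM-co-GMA matrix of thickness ``matrix_level``.  This module provides the
cap identities (base radius, horizontal slice radius, projected exposed area),
summary statistics of a field of caps in the style of a surface-characterisation
table (median/IQR heights, nearest-neighbour spacing, number density, exposed
area and coverage), and the mapping between reduced simulation lengths and
nanometres.

All heights are measured from a zero-set basal plane, i.e. after the basal
roughness background has been subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InvalidCapError",
    "SphericalCap",
    "SphericalCapField",
    "SurfaceStats",
    "UnitMap",
    "cap_base_radius",
    "cap_slice_radius",
    "exposed_area",
    "swelling_ratio",
    "surface_stats",
    "unit_map_from_heights",
    "surface_stats_table",
]


class InvalidCapError(ValueError):
    """Raised when cap parameters violate the spherical-cap constraints."""


@dataclass(frozen=True)
class SphericalCap:
    """A spherical cap: sphere radius ``R_sp``, cap height ``H``, lateral center.

    Units are whatever the caller uses consistently (nm for experiment-like
    fields, reduced units for simulation output).  Requires ``0 <= H <= 2 R_sp``.
    """

    R_sp: float
    H: float
    center_xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.R_sp > 0 and np.isfinite(self.R_sp)):
            raise InvalidCapError(f"R_sp must be positive, got {self.R_sp}")
        if self.H < 0 or self.H > 2.0 * self.R_sp:
            raise InvalidCapError(
                f"cap height H={self.H} outside [0, 2*R_sp]={2 * self.R_sp}"
            )


@dataclass
class SphericalCapField:
    """A set of spherical-cap domains plus the matrix level, on a finite field.

    ``field_size`` is the (Lx, Ly) extent of the observed area in the same
    lateral units as the cap centers.  ``matrix_level`` is the height of the
    near-uniform matrix phase above the basal plane.
    """

    caps: list[SphericalCap]
    field_size: tuple[float, float]
    matrix_level: float = 0.0

    @property
    def centers(self) -> np.ndarray:
        return np.array([c.center_xy for c in self.caps], dtype=float).reshape(-1, 2)

    @property
    def heights(self) -> np.ndarray:
        return np.array([c.H for c in self.caps], dtype=float)


@dataclass
class SurfaceStats:
    """Summary statistics of a cap field, one row of a characterisation table.

    Heights in nm, areas in um^2, densities in um^-2 unless the field was built
    in reduced units (then the same numbers carry reduced units).
    """

    H_median: float
    H_iqr: float
    h_matrix_air: float
    h_matrix_below_lcst: float | None
    swelling_ratio: float | None
    d_neighbor: float
    d_neighbor_iqr: float
    rho_domains: float
    A_exposed_median: float
    A_exposed_iqr: float
    coverage_rhoA: float
    n_domains: int = 0
    n_domains_for_d: int = 0


@dataclass(frozen=True)
class UnitMap:
    """Nanometres per reduced length unit, separately for heights and lateral radii.

    Simulated phase-separated domains are less immersed in the substrate than
    fabricated ones, so a single isotropic scale factor cannot match both the
    cap heights and the base radii; the ratio ``anisotropy`` quantifies that.
    """

    sigma_height: float
    sigma_lateral: float

    def __post_init__(self) -> None:
        if self.sigma_height <= 0 or self.sigma_lateral <= 0:
            raise ValueError("unit-map scale factors must be strictly positive")

    @property
    def anisotropy(self) -> float:
        """sigma_lateral / sigma_height."""
        return self.sigma_lateral / self.sigma_height


def cap_base_radius(cap: SphericalCap) -> float:
    """Radius of the circle where the cap meets the basal plane.

    For a cap of height H on a sphere of radius R_sp this is
    ``sqrt(H * (2 R_sp - H))``; equal to R_sp for a hemisphere, 0 for H = 0.
    """
    return float(np.sqrt(cap.H * (2.0 * cap.R_sp - cap.H)))


def cap_slice_radius(cap: SphericalCap, h_slice: float) -> float:
    """Radius of the horizontal slice of the cap at height ``h_slice`` above its base.

    ``sqrt(R_sp^2 - (R_sp - H + h_slice)^2)`` for ``0 <= h_slice <= H``; equals
    the base radius at h_slice = 0 and vanishes at the apex h_slice = H.
    """
    if h_slice < 0 or h_slice > cap.H:
        raise ValueError(f"h_slice={h_slice} outside [0, H]=[0, {cap.H}]")
    d = cap.R_sp - cap.H + h_slice
    arg = cap.R_sp * cap.R_sp - d * d
    return float(np.sqrt(max(arg, 0.0)))


def exposed_area(cap: SphericalCap, matrix_level: float) -> float:
    """Projected area of the part of the cap standing above the matrix level.

    The matrix buries the cap up to ``matrix_level``; the exposed part projects
    onto a disc of radius ``cap_slice_radius(cap, matrix_level)``.  Zero when
    the cap is fully buried.
    """
    if matrix_level < 0:
        raise ValueError("matrix_level must be >= 0 (background-subtracted heights)")
    if matrix_level >= cap.H:
        return 0.0
    r = cap_slice_radius(cap, matrix_level)
    return float(np.pi * r * r)


def swelling_ratio(h_below: float, h_air: float, ndigits: int | None = None) -> float:
    """Swelling ratio of the thermoresponsive matrix: height below LCST over height in air.

    Parameters
    ----------
    h_below, h_air
        Matrix heights (nm) in water below the LCST and in air (collapsed).
    ndigits
        Optional rounding, e.g. 1 to emulate a printed table column.
    """
    if h_air <= 0:
        raise ZeroDivisionError("h_air must be strictly positive")
    r = h_below / h_air
    return round(r, ndigits) if ndigits is not None else r


def _nn4_distances(centers: np.ndarray, field_size: tuple[float, float]) -> np.ndarray:
    """Per-domain mean distance to its 4 nearest neighbours, with edge exclusion.

    The field is finite (like a real scan), so domains whose 4-NN search radius
    would cross the field border are excluded rather than wrapped.
    Returns the array of retained per-domain mean distances.
    """
    from scipy.spatial import cKDTree

    tree = cKDTree(centers)
    # 5 = self + 4 neighbours
    dist, _ = tree.query(centers, k=5)
    d4 = dist[:, 1:]
    mean_d = d4.mean(axis=1)
    rmax = d4.max(axis=1)
    lx, ly = field_size
    x, y = centers[:, 0], centers[:, 1]
    border = np.minimum.reduce([x, lx - x, y, ly - y])
    keep = rmax <= border
    if not np.any(keep):
        # degenerate tiny field: fall back to all domains rather than none
        keep = np.ones(len(centers), dtype=bool)
    return mean_d[keep]


def surface_stats(
    field: SphericalCapField,
    h_matrix_below_lcst: float | None = None,
    area_unit: float = 1.0,
) -> SurfaceStats:
    """Table-style summary statistics of a spherical-cap field.

    Computes the median and interquartile range of cap heights, the mean
    distance to the 4 nearest domain centers (finite-field edge exclusion),
    the domain number density, the median exposed area above the matrix, and
    the coverage ``density * median exposed area``.

    Parameters
    ----------
    field
        Cap field with lateral sizes and matrix level in consistent units.
    h_matrix_below_lcst
        Optional swollen matrix height; enables the swelling-ratio column.
    area_unit
        Lateral length units per micrometre (e.g. 1000 for nm fields).
        Densities are reported per ``area_unit**2`` and areas in units of
        ``area_unit**2`` so nm-based fields report um^-2 and um^2.

    Notes
    -----
    Median/IQR are used throughout (not mean/SD): domain height distributions
    on these surfaces are broad and skewed.
    """
    if len(field.caps) < 5:
        raise ValueError(
            f"need >= 5 domains for 4-nearest-neighbour statistics, got {len(field.caps)}"
        )
    heights = field.heights
    q25, q50, q75 = np.percentile(heights, [25, 50, 75])
    areas = np.array([exposed_area(c, field.matrix_level) for c in field.caps])
    a25, a50, a75 = np.percentile(areas, [25, 50, 75])
    d_arr = _nn4_distances(field.centers, field.field_size)
    lx, ly = field.field_size
    area_field_um2 = (lx / area_unit) * (ly / area_unit)
    rho = len(field.caps) / area_field_um2
    a50_um2 = a50 / area_unit**2
    a_iqr_um2 = (a75 - a25) / area_unit**2
    sw = None
    if h_matrix_below_lcst is not None and field.matrix_level > 0:
        sw = swelling_ratio(h_matrix_below_lcst, field.matrix_level)
    return SurfaceStats(
        H_median=float(q50),
        H_iqr=float(q75 - q25),
        h_matrix_air=float(field.matrix_level),
        h_matrix_below_lcst=h_matrix_below_lcst,
        swelling_ratio=sw,
        d_neighbor=float(np.mean(d_arr)),
        d_neighbor_iqr=float(np.subtract(*np.percentile(d_arr, [75, 25]))),
        rho_domains=float(rho),
        A_exposed_median=float(a50_um2),
        A_exposed_iqr=float(a_iqr_um2),
        coverage_rhoA=float(rho * a50_um2),
        n_domains=len(field.caps),
        n_domains_for_d=len(d_arr),
    )


def unit_map_from_heights(
    H_exp_nm: float, H_sim: float, Rd_exp_nm: float, Rd_sim: float
) -> UnitMap:
    """Length-scale calibration between simulated and fabricated domains.

    Matching cap heights gives ``sigma_height = H_exp / H_sim`` (nm per reduced
    unit); matching base radii gives an independent ``sigma_lateral``.  The two
    differ when simulated domains are less immersed in the substrate than the
    fabricated ones; ``UnitMap.anisotropy`` reports the ratio.
    """
    for name, v in (
        ("H_exp_nm", H_exp_nm),
        ("H_sim", H_sim),
        ("Rd_exp_nm", Rd_exp_nm),
        ("Rd_sim", Rd_sim),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be strictly positive, got {v}")
    return UnitMap(sigma_height=H_exp_nm / H_sim, sigma_lateral=Rd_exp_nm / Rd_sim)


#: Column names used when emulating the characterisation table.
TABLE_COLUMNS = [
    "H_PGMA",
    "h_PNIPAM air",
    "h_PNIPAM below LCST",
    "Swelling ratio",
    "d",
    "rho",
    "A",
    "rhoxA",
]


def surface_stats_table(stats: dict[str, SurfaceStats]) -> pd.DataFrame:
    """Assemble named SurfaceStats rows into a characterisation table.

    Swelling ratios are rounded to one decimal as printed in such tables;
    heights keep one decimal, coverage two.
    """
    rows = {}
    for name, s in stats.items():
        rows[name] = {
            "H_PGMA": round(s.H_median, 1),
            "h_PNIPAM air": round(s.h_matrix_air, 1),
            "h_PNIPAM below LCST": (
                round(s.h_matrix_below_lcst, 1)
                if s.h_matrix_below_lcst is not None
                else float("nan")
            ),
            "Swelling ratio": (
                round(s.swelling_ratio, 1) if s.swelling_ratio is not None else float("nan")
            ),
            "d": round(s.d_neighbor, 0),
            "rho": round(s.rho_domains, 1),
            "A": round(s.A_exposed_median, 3),
            "rhoxA": round(s.coverage_rhoA, 2),
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=TABLE_COLUMNS)
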