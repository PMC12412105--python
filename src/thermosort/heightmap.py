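"""Synthetic SPM-like height maps of cap-decorated surfaces, and their analysis.

The generator emulates scanning-probe height images of microstructured
thermoresponsive coatings: spherical-cap domains with a broad height
distribution rise above a near-uniform matrix level on a rough basal plane.
Caps are placed by random sequential adsorption (no base-disc overlap) and
rendered as ``max(basal plane + noise, matrix level + noise, cap surface)``.
The ground-truth :class:`~thermosort.capgeom.SphericalCapField` is returned
alongside, so the analysis path can be validated without any instrument data.

The analyzer inverts the rendering: it subtracts a background level, labels
connected pixel regions above a set of horizontal slice levels, and fits each
domain with the spherical-cap relation

    r^2(h) = R_sp^2 - (R_sp - H + h)^2 = 2 R_sp (H - h) - (H - h)^2

by least squares across slices, where ``r(h)`` is the equivalent-disc radius
``sqrt(area / pi)`` of the domain's cross-section at height ``h``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

from .capgeom import SphericalCap, SphericalCapField

__all__ = [
    "HeightMap",
    "GeneratorSpec",
    "PlacementError",
    "generate",
    "analyze",
    "write_heightmap",
    "read_heightmap",
]


class PlacementError(RuntimeError):
    """Random sequential adsorption could not reach the requested density."""


@dataclass
class HeightMap:
    """A raster grid of surface heights (nm) with pixel-size metadata.

    ``pixel_size`` is nm per pixel; ``field_size_um`` the scan edge length in
    micrometres.  Grid shapes follow typical SPM scan resolutions
    (256x256 up to 1024x1024).
    """

    grid: np.ndarray
    pixel_size: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("height map grid must be 2-D")
        for n in self.grid.shape:
            if not (256 <= n <= 1024):
                raise ValueError(
                    f"grid dimension {n} outside the supported scan range [256, 1024]"
                )
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("height map contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def field_size_um(self) -> tuple[float, float]:
        ny, nx = self.grid.shape
        return (nx * self.pixel_size / 1000.0, ny * self.pixel_size / 1000.0)


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic surface generator.

    Defaults emulate a mid-range microstructured sample: domain density
    ~6.5 um^-2, cap heights with median ~41.5 nm and IQR ~7.4 nm, matrix level
    ~19.4 nm, basal roughness 5 nm (typical range 3-7 nm).  Cap sphere radii
    follow from heights through the aspect ratio ``R_sp / H``; the default
    aspect keeps the base discs placeable without overlap at these densities
    (fabricated domains are flatter still, but their crowded bases are buried
    under the matrix, while the generator enforces strict non-overlap).
    """

    density_um2: float = 6.5
    height_median_nm: float = 41.5
    height_iqr_nm: float = 7.4
    rsp_over_h: float = 4.0
    rsp_over_h_spread: float = 0.5
    matrix_level_nm: float = 19.4
    matrix_noise_nm: float = 0.5
    basal_roughness_nm: float = 5.0
    field_size_um: float = 10.0
    grid_size: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_um2 < 0:
            raise ValueError("density must be >= 0")
        if self.height_median_nm <= 0 or self.height_iqr_nm < 0:
            raise ValueError("height distribution parameters must be positive")
        if not (0.0 <= self.basal_roughness_nm <= 10.0):
            raise ValueError("basal roughness outside the supported 0-10 nm range")
        if self.rsp_over_h <= 0.5:
            raise ValueError("rsp_over_h must exceed 0.5 (H <= 2 R_sp)")


def _lognormal_sigma_from_iqr(median: float, iqr: float) -> float:
    """Log-normal shape parameter with the requested median and IQR."""
    if iqr == 0:
        return 0.0
    z = 0.674489750196  # standard normal 75th percentile
    f = lambda s: median * (np.exp(z * s) - np.exp(-z * s)) - iqr
    return float(optimize.brentq(f, 1e-9, 5.0))


def _sample_caps(spec: GeneratorSpec, rng: np.random.Generator) -> list[SphericalCap]:
    """RSA placement of caps: draw heights/radii, place without base-disc overlap."""
    area_um2 = spec.field_size_um**2
    n_target = int(round(spec.density_um2 * area_um2))
    if n_target == 0:
        return []
    L = spec.field_size_um * 1000.0  # nm
    sigma = _lognormal_sigma_from_iqr(spec.height_median_nm, spec.height_iqr_nm)
    heights = spec.height_median_nm * np.exp(sigma * rng.standard_normal(n_target))
    aspect = np.clip(
        rng.normal(spec.rsp_over_h, spec.rsp_over_h_spread, n_target), 0.6, None
    )
    rsps = aspect * heights
    base_r = np.sqrt(heights * (2.0 * rsps - heights))

    caps: list[SphericalCap] = []
    placed_xy = np.empty((0, 2))
    placed_r = np.empty(0)
    max_attempts = 300 * n_target
    stall_limit = 20_000 + 10 * n_target  # attempts without a success => jammed
    attempts = 0
    since_success = 0
    i = 0
    while i < n_target:
        if attempts >= max_attempts or since_success >= stall_limit:
            raise PlacementError(
                f"placed only {i}/{n_target} domains after {attempts} attempts; "
                "requested density unreachable without overlap"
            )
        attempts += 1
        since_success += 1
        xy = rng.uniform(0.0, L, size=2)
        if len(placed_xy):
            d = np.hypot(*(placed_xy - xy).T)
            if np.any(d < placed_r + base_r[i]):
                continue
        caps.append(SphericalCap(R_sp=float(rsps[i]), H=float(heights[i]), center_xy=tuple(xy)))
        placed_xy = np.vstack([placed_xy, xy])
        placed_r = np.append(placed_r, base_r[i])
        since_success = 0
        i += 1
    return caps


def generate(spec: GeneratorSpec) -> tuple[HeightMap, SphericalCapField]:
    """Render a synthetic height map and return it with its ground-truth cap field.

    Per-pixel height is ``max(basal noise, matrix level + noise, cap surface)``;
    the basal and matrix noises are independent Gaussians (the instrument-like
    roughness amplitude is all the generator models).  Fixed seed gives a
    bit-identical map.
    """
    rng = np.random.default_rng(spec.seed)
    caps = _sample_caps(spec, rng)
    n = spec.grid_size
    L = spec.field_size_um * 1000.0
    px = L / n

    basal = rng.normal(0.0, spec.basal_roughness_nm, size=(n, n))
    matrix = rng.normal(spec.matrix_level_nm, spec.matrix_noise_nm, size=(n, n))
    grid = np.maximum(basal, matrix)

    # pixel-center coordinates, origin at the map corner, y downward
    xs = (np.arange(n) + 0.5) * px
    for cap in caps:
        cx, cy = cap.center_xy
        rb = np.sqrt(cap.H * (2.0 * cap.R_sp - cap.H))
        i0 = max(int((cy - rb) / px) - 1, 0)
        i1 = min(int((cy + rb) / px) + 2, n)
        j0 = max(int((cx - rb) / px) - 1, 0)
        j1 = min(int((cx + rb) / px) + 2, n)
        if i0 >= i1 or j0 >= j1:
            continue
        dx = xs[j0:j1] - cx
        dy = xs[i0:i1] - cy
        d2 = dy[:, None] ** 2 + dx[None, :] ** 2
        inside = d2 < rb * rb
        zc = cap.H - cap.R_sp + np.sqrt(np.maximum(cap.R_sp**2 - d2, 0.0))
        sub = grid[i0:i1, j0:j1]
        np.maximum(sub, np.where(inside, zc, -np.inf), out=sub)

    meta = {
        "generator": "thermosort.heightmap.generate",
        "seed": spec.seed,
        "density_um2": spec.density_um2,
        "height_median_nm": spec.height_median_nm,
        "height_iqr_nm": spec.height_iqr_nm,
        "rsp_over_h": spec.rsp_over_h,
        "matrix_level_nm": spec.matrix_level_nm,
        "basal_roughness_nm": spec.basal_roughness_nm,
        "field_size_um": spec.field_size_um,
        "n_domains": len(caps),
    }
    hm = HeightMap(grid=grid, pixel_size=px, metadata=meta)
    truth = SphericalCapField(
        caps=caps,
        field_size=(L, L),
        matrix_level=spec.matrix_level_nm,
    )
    return hm, truth


def _fit_rsp(h_rel: np.ndarray, r: np.ndarray) -> float:
    """Least-squares R_sp from slice radii: r^2 = 2 R (H-h) - (H-h)^2.

    ``h_rel = H - h`` is the depth of each slice below the domain apex.  The
    relation is linear in R through the origin after moving the quadratic term
    to the left: (r^2 + h_rel^2) = 2 R h_rel.
    """
    x = 2.0 * h_rel
    y = r * r + h_rel * h_rel
    denom = float(np.dot(x, x))
    if denom == 0.0:
        return float("nan")
    return float(np.dot(x, y) / denom)


def analyze(
    hmap: HeightMap,
    slice_levels: np.ndarray | list[float] | None = None,
    background_quantile: float = 0.10,
    min_pixels: int = 4,
) -> SphericalCapField:
    """Recover a spherical-cap field from a height map by horizontal slicing.

    The background is estimated as a low quantile of all heights and
    subtracted.  Pixels above the lowest slice level are grouped into
    8-connected components (caps are convex blobs; 8-connectivity avoids
    spurious splits at diagonal pixels); components touching the map border
    are dropped (partial caps bias both H and R_sp).  For each retained
    domain the pixel count above every slice level gives an equivalent-disc
    radius, and R_sp follows from the cap relation by least squares.

    Parameters
    ----------
    slice_levels
        Heights (nm, background-subtracted) of the virtual slices.  Default:
        5 evenly spaced levels between the matrix level (median height) and
        90% of the maximum height.
    """
    grid = hmap.grid - np.quantile(hmap.grid, background_quantile)
    matrix_est = float(np.median(grid))
    if slice_levels is None:
        # noise floor from the MAD of the matrix-dominated histogram: the lowest
        # slice must clear the matrix noise or its pixels percolate into one
        # border-touching component
        sigma_n = 1.4826 * float(np.median(np.abs(grid - matrix_est)))
        base = matrix_est + max(5.0 * sigma_n, 1e-9)
        top = 0.9 * float(grid.max())
        if top <= base:
            return SphericalCapField(caps=[], field_size=_field_nm(hmap), matrix_level=matrix_est)
        slice_levels = np.linspace(base, top, 5)
    levels = np.sort(np.asarray(slice_levels, dtype=float))
    if len(levels) < 2:
        raise ValueError("need at least 2 slice levels above the matrix")

    base_level = levels[0]
    labels, n_lab = ndimage.label(grid > base_level, structure=np.ones((3, 3), int))
    if n_lab == 0:
        return SphericalCapField(caps=[], field_size=_field_nm(hmap), matrix_level=matrix_est)

    border = np.zeros_like(labels, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    edge_labels = np.unique(labels[border])
    px = hmap.pixel_size

    objects = ndimage.find_objects(labels)
    caps: list[SphericalCap] = []
    for lab in range(1, n_lab + 1):
        if lab in edge_labels:
            continue
        sl = objects[lab - 1]
        mask = labels[sl] == lab
        if mask.sum() < min_pixels:
            continue
        sub = grid[sl]
        H = float(sub[mask].max())
        iy, ix = np.nonzero(mask)
        cy = (sl[0].start + iy.mean() + 0.5) * px
        cx = (sl[1].start + ix.mean() + 0.5) * px
        h_rel, rads = [], []
        for lv in levels:
            if lv >= H:
                continue
            npix = int(np.count_nonzero(sub[mask] > lv))
            if npix == 0:
                continue
            h_rel.append(H - lv)
            rads.append(np.sqrt(npix * px * px / np.pi))
        if len(h_rel) < 2:
            continue
        rsp = _fit_rsp(np.asarray(h_rel), np.asarray(rads))
        if not np.isfinite(rsp) or rsp < H / 2.0:
            rsp = max(H, 1e-9)  # degenerate fit: steepest admissible cap
        caps.append(SphericalCap(R_sp=rsp, H=H, center_xy=(cx, cy)))
    return SphericalCapField(caps=caps, field_size=_field_nm(hmap), matrix_level=matrix_est)


def _field_nm(hmap: HeightMap) -> tuple[float, float]:
    ny, nx = hmap.grid.shape
    return (nx * hmap.pixel_size, ny * hmap.pixel_size)


def write_heightmap(hmap: HeightMap, prefix: str | Path) -> tuple[Path, Path]:
    """Write a height map as a plain-text matrix plus a JSON sidecar.

    The matrix file holds rows of whitespace-separated nm values at full
    float precision, so read/write round trips are bit-exact.
    """
    prefix = Path(prefix)
    dat = prefix.with_suffix(".txt")
    meta = prefix.with_suffix(".json")
    np.savetxt(dat, hmap.grid, fmt="%.17g")
    sidecar = {"pixel_size_nm": hmap.pixel_size, "metadata": hmap.metadata}
    meta.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return dat, meta


def read_heightmap(prefix: str | Path) -> HeightMap:
    """Read a height map written by :func:`write_heightmap`."""
    prefix = Path(prefix)
    grid = np.loadtxt(prefix.with_suffix(".txt"))
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    return HeightMap(
        grid=grid, pixel_size=sidecar["pixel_size_nm"], metadata=sidecar.get("metadata", {})
    )
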