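"""Spherical-cap geometry and table-style surface statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermosort import capgeom as cg


@pytest.mark.parametrize(
    "R, H, expected",
    [
        (50.0, 50.0, 50.0),  # hemisphere: base radius equals sphere radius
        (50.0, 0.0, 0.0),
        (100.0, 20.0, 60.0),  # sqrt(20 * 180)
    ],
)
def test_base_radius(R, H, expected):
    assert cg.cap_base_radius(cg.SphericalCap(R, H)) == pytest.approx(expected)


def test_invalid_caps_rejected():
    with pytest.raises(cg.InvalidCapError):
        cg.SphericalCap(50.0, 101.0)
    with pytest.raises(cg.InvalidCapError):
        cg.SphericalCap(-1.0, 0.5)


def test_slice_radius_closed_form_and_ends():
    cap = cg.SphericalCap(100.0, 20.0)
    assert cg.cap_slice_radius(cap, 10.0) == pytest.approx(43.589, abs=1e-3)
    assert cg.cap_slice_radius(cap, 0.0) == pytest.approx(cg.cap_base_radius(cap))
    assert cg.cap_slice_radius(cap, cap.H) == 0.0
    with pytest.raises(ValueError):
        cg.cap_slice_radius(cap, 21.0)


def test_exposed_area_cases():
    cap = cg.SphericalCap(100.0, 20.0)
    assert cg.exposed_area(cap, 25.0) == 0.0  # fully buried
    assert cg.exposed_area(cap, 0.0) == pytest.approx(
        math.pi * cg.cap_base_radius(cap) ** 2
    )
    assert cg.exposed_area(cap, 10.0) == pytest.approx(math.pi * 43.589**2, rel=1e-4)


def test_exposed_area_matches_point_sampling():
    """Projected exposed area agrees with uniform sampling over the footprint."""
    cap = cg.SphericalCap(100.0, 20.0)
    rng = np.random.default_rng(0)
    rb = cg.cap_base_radius(cap)
    pts = rng.uniform(-rb, rb, (100_000, 2))
    inside = np.hypot(pts[:, 0], pts[:, 1]) <= rb
    # height of the cap surface above the base at radial distance d
    d = np.hypot(pts[inside, 0], pts[inside, 1])
    zc = cap.H - cap.R_sp + np.sqrt(cap.R_sp**2 - d**2)
    for level in (5.0, 10.0, 15.0):
        est = np.mean(zc > level) * np.mean(inside) * (2 * rb) ** 2
        assert cg.exposed_area(cap, level) == pytest.approx(est, rel=0.01)


@settings(derandomize=True, max_examples=50)
@given(
    R=st.floats(1.0, 1e3),
    frac=st.floats(0.01, 1.0),  # up to a hemisphere, as for fabricated domains
    s=st.floats(0.0, 1.0),
)
def test_cap_identities_property(R, frac, s):
    """Slice at 0 equals the base radius; slice radius decreases with height."""
    cap = cg.SphericalCap(R, frac * R)
    assert cg.cap_slice_radius(cap, 0.0) == pytest.approx(
        cg.cap_base_radius(cap), rel=1e-12, abs=1e-12
    )
    h1 = s * cap.H * 0.5
    h2 = cap.H * (0.5 + 0.5 * s)
    if h2 > h1:
        assert cg.cap_slice_radius(cap, h2) <= cg.cap_slice_radius(cap, h1) + 1e-9


def test_swelling_ratio_table_rows():
    assert cg.swelling_ratio(57.7, 16.7, ndigits=1) == 3.5
    assert cg.swelling_ratio(113.2, 51.5, ndigits=1) == 2.2
    assert cg.swelling_ratio(10.0, 10.0) == 1.0
    with pytest.raises(ZeroDivisionError):
        cg.swelling_ratio(1.0, 0.0)


def test_surface_stats_lattice_and_density():
    # 10x10 square lattice, pitch 500 nm on a 5x5 um field
    pitch = 500.0
    caps = [
        cg.SphericalCap(200.0, 50.0, center_xy=(pitch * (i + 0.5), pitch * (j + 0.5)))
        for i in range(10)
        for j in range(10)
    ]
    field = cg.SphericalCapField(caps, field_size=(5000.0, 5000.0), matrix_level=20.0)
    stats = cg.surface_stats(field, area_unit=1000.0)
    assert stats.d_neighbor == pytest.approx(pitch)
    assert stats.rho_domains == pytest.approx(100 / 25.0)
    assert stats.H_median == pytest.approx(50.0)
    assert 0.0 <= stats.coverage_rhoA < 1.0


def test_surface_stats_requires_five_domains():
    caps = [cg.SphericalCap(10.0, 5.0, (float(i), 0.0)) for i in range(4)]
    with pytest.raises(ValueError):
        cg.surface_stats(cg.SphericalCapField(caps, (10.0, 10.0)))


def test_unit_map():
    um = cg.unit_map_from_heights(90.0, 10.0, 360.0, 10.0)
    assert um.sigma_height == pytest.approx(9.0)
    assert um.anisotropy == pytest.approx(4.0)
    assert cg.unit_map_from_heights(5.0, 5.0, 7.0, 7.0).sigma_height == 1.0
    with pytest.raises(ValueError):
        cg.unit_map_from_heights(-1.0, 1.0, 1.0, 1.0)


def test_table_output_columns():
    caps = [cg.SphericalCap(200.0, 50.0, (100.0 * i, 70.0 * i)) for i in range(1, 8)]
    field = cg.SphericalCapField(caps, (1000.0, 1000.0), matrix_level=19.4)
    stats = cg.surface_stats(field, h_matrix_below_lcst=40.0, area_unit=1000.0)
    table = cg.surface_stats_table({"B1": stats})
    assert list(table.columns) == cg.TABLE_COLUMNS
    assert table.loc["B1", "Swelling ratio"] == pytest.approx(2.1)
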