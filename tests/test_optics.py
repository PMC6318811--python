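"""Optical-property formulas against their published/tabulated values.

All golden numbers are printed table entries of the source model; the
stated tolerance for tabulated optical coefficients is +/-0.005 mm^-1
(values are printed to 2-3 decimals) and +/-1 uM for ICG concentrations.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pwstherm.optics import (
    DERMIS_DEPTH_BINS,
    PIGMENTATION_LEVELS,
    NETFormulation,
    OpticalProperties,
    blood_properties,
    icg_for_target_mu_a,
    mu_a_basal,
    mu_a_baseline,
    mu_a_dermis_adjusted,
    mu_a_dermis_oct,
    mu_a_melanosome,
    mu_s_skin,
    skin_anisotropy,
    vessel_effective_properties,
    vessel_screening_factor,
)

TOL_MU = 0.005  # mm^-1, printed to 3 decimals
TOL_BASAL = 0.05  # mm^-1; basal-layer entries are printed to 2 decimals
TOL_ICG = 1.0  # uM


# ---------------------------------------------------------------- baseline/epidermis
@pytest.mark.parametrize("wavelength,expected", [(585.0, 0.037), (755.0, 0.025)])
def test_mu_a_baseline_tabulated(wavelength, expected):
    assert mu_a_baseline(wavelength) == pytest.approx(expected, abs=TOL_MU)


def test_mu_a_baseline_long_wavelength_asymptote():
    # the exponential term dies off; the floor is the 0.0244 constant
    assert mu_a_baseline(1100.0) == pytest.approx(0.0244, abs=1e-4)


def test_mu_a_melanosome_decreases_with_wavelength():
    assert mu_a_melanosome(585.0) > mu_a_melanosome(755.0) > 0


@pytest.mark.parametrize(
    "wavelength,fmel,expected",
    [
        (585.0, 0.04, 1.65),
        (585.0, 0.15, 6.07),
        (585.0, 0.50, 20.15),
        (755.0, 0.04, 0.71),
        (755.0, 0.15, 2.58),
        (755.0, 0.50, 8.61),
    ],
)
def test_mu_a_basal_tabulated(wavelength, fmel, expected):
    assert mu_a_basal(wavelength, fmel) == pytest.approx(expected, abs=TOL_BASAL)


def test_mu_a_basal_reduces_to_baseline_without_melanin():
    assert mu_a_basal(585.0, 0.0) == pytest.approx(mu_a_baseline(585.0), rel=1e-12)


def test_wavelength_range_check():
    with pytest.raises(ValueError):
        mu_a_baseline(300.0)
    with pytest.raises(ValueError):
        mu_s_skin(2000.0)


# ---------------------------------------------------------------- scattering
@pytest.mark.parametrize("wavelength,expected", [(585.0, 15.61), (755.0, 17.55)])
def test_mu_s_skin_tabulated(wavelength, expected):
    assert mu_s_skin(wavelength) == pytest.approx(expected, abs=TOL_MU)


def test_skin_anisotropy_tabulated():
    assert skin_anisotropy(585.0) == pytest.approx(0.80)
    assert skin_anisotropy(755.0) == pytest.approx(0.91)


def test_mu_s_skin_invalid_anisotropy():
    with pytest.raises(ValueError):
        mu_s_skin(585.0, g=1.0)


# ---------------------------------------------------------------- blood
def test_blood_properties_tabulated():
    b585 = blood_properties(585.0)
    assert (b585.mu_a, b585.mu_s, b585.g) == pytest.approx((17.91, 76.05, 0.970))
    b755 = blood_properties(755.0)
    assert (b755.mu_a, b755.mu_s, b755.g) == pytest.approx((0.44, 79.85, 0.983))


def test_blood_properties_untabulated_wavelength_raises():
    with pytest.raises(ValueError):
        blood_properties(600.0)


# ---------------------------------------------------------------- screening + dermis
def test_screening_factor_limits():
    # zero optical depth: sum of the three fit coefficients
    assert vessel_screening_factor(0.0, 25.0) == pytest.approx(0.993, abs=1e-3)
    # fully screened: only the constant term survives
    assert vessel_screening_factor(50.0, 500.0) == pytest.approx(0.039, abs=1e-3)


def test_screening_factor_monotone_in_radius():
    # small optical depth so the factor is not saturated at its 0.039 floor
    values = [vessel_screening_factor(0.01, r) for r in (5, 10, 20, 40, 80)]
    assert all(a > b for a, b in zip(values, values[1:]))
    assert all(0.039 <= v <= 0.994 for v in values)


@pytest.mark.parametrize(
    "wavelength,expected_by_bin",
    [
        (585.0, (0.071, 0.090, 0.062, 0.053, 0.050, 0.047)),
        (755.0, (0.025, 0.024, 0.025, 0.025, 0.025, 0.025)),
    ],
)
def test_mu_a_dermis_adjusted_table(wavelength, expected_by_bin):
    for depth_bin, expected in zip(DERMIS_DEPTH_BINS, expected_by_bin):
        value = mu_a_dermis_adjusted(wavelength, depth_bin)
        assert value == pytest.approx(expected, abs=TOL_MU), depth_bin


@pytest.mark.parametrize("wavelength,expected", [(585.0, 0.073), (755.0, 0.026)])
def test_mu_a_dermis_oct_tabulated(wavelength, expected):
    assert mu_a_dermis_oct(wavelength) == pytest.approx(expected, abs=TOL_MU)


def test_mu_a_dermis_oct_validates_fraction():
    with pytest.raises(ValueError):
        mu_a_dermis_oct(585.0, f_blood=1.5)


# ---------------------------------------------------------------- NETs / vessels
def test_vessel_effective_identity_without_nets():
    blood = blood_properties(755.0)
    assert vessel_effective_properties(blood, None) is blood


@pytest.mark.parametrize(
    "kind,f,expected_mu_s",
    [("nano", 0.25, 59.90), ("micro", 0.10, 72.09)],
)
def test_vessel_effective_mu_s_bounds(kind, f, expected_mu_s):
    blood = blood_properties(755.0)
    net = NETFormulation.for_target_mu_a_bv(kind, f, 6.0, 755.0)
    eff = vessel_effective_properties(blood, net)
    # +1e-9 absorbs the half-ULP case: 72.085 prints as 72.09, |diff| == 0.005
    assert eff.mu_s == pytest.approx(expected_mu_s, abs=TOL_MU + 1e-9)


@pytest.mark.parametrize(
    "target,f,expected",
    [
        (18.0, 0.25, 1258.0),
        (1.0, 0.10, 108.0),
        (2.0, 0.10, 286.0),
        (3.0, 0.10, 464.0),
        (4.0, 0.10, 642.0),
        (5.0, 0.10, 820.0),
        (6.0, 0.10, 998.0),
    ],
)
def test_icg_concentration_tabulated(target, f, expected):
    value = icg_for_target_mu_a(target, f, 0.44)
    assert value == pytest.approx(expected, abs=TOL_ICG)


def test_icg_infeasible_target_raises():
    with pytest.raises(ValueError, match="infeasible"):
        icg_for_target_mu_a(0.1, 0.10, 0.44)


def test_net_formulation_round_trip():
    blood = blood_properties(755.0)
    net = NETFormulation.for_target_mu_a_bv("micro", 0.10, 3.0, 755.0)
    eff = vessel_effective_properties(blood, net)
    assert eff.mu_a == pytest.approx(3.0, rel=1e-12)
    assert net.icg_concentration == pytest.approx(
        icg_for_target_mu_a(3.0, 0.10, blood.mu_a), rel=1e-12
    )


def test_net_kinds_have_published_scattering():
    micro = NETFormulation.for_target_mu_a_bv("micro", 0.10, 3.0, 755.0)
    nano = NETFormulation.for_target_mu_a_bv("nano", 0.10, 3.0, 755.0)
    assert (micro.mu_s_nets, micro.g_nets) == pytest.approx((2.20, 0.99))
    assert (nano.mu_s_nets, nano.g_nets) == pytest.approx((0.06, 0.55))


def test_pigmentation_levels():
    assert PIGMENTATION_LEVELS["light"].fmel == pytest.approx(0.04)
    assert PIGMENTATION_LEVELS["moderate"].fmel == pytest.approx(0.15)
    assert PIGMENTATION_LEVELS["heavy"].fmel == pytest.approx(0.50)


# ---------------------------------------------------------------- properties
@settings(max_examples=50, deadline=None)
@given(
    f=st.floats(0.01, 1.0),
    target=st.floats(0.5, 30.0),
)
def test_icg_forward_inverse_consistency(f, target):
    blood = blood_properties(755.0)
    minimum = (1.0 - f) * blood.mu_a
    if target < minimum:
        target = minimum + 0.1
    net = NETFormulation.for_target_mu_a_bv("micro", f, target, 755.0)
    eff = vessel_effective_properties(blood, net)
    assert eff.mu_a == pytest.approx(target, rel=1e-9)


@settings(max_examples=50, deadline=None)
@given(f=st.floats(0.0, 1.0))
def test_vessel_mixing_is_bounded_by_components(f):
    blood = blood_properties(755.0)
    if f == 0.0:
        return
    net = NETFormulation(kind="nano", f_nets=f, mu_a_nets=5.0)
    eff = vessel_effective_properties(blood, net)
    for attr in ("mu_a", "mu_s", "g"):
        lo = min(getattr(blood, attr), {"mu_a": 5.0, "mu_s": 0.06, "g": 0.55}[attr])
        hi = max(getattr(blood, attr), {"mu_a": 5.0, "mu_s": 0.06, "g": 0.55}[attr])
        assert lo - 1e-12 <= getattr(eff, attr) <= hi + 1e-12


def test_optical_properties_validation():
    with pytest.raises(ValueError):
        OpticalProperties(-1.0, 10.0, 0.9)
    with pytest.raises(ValueError):
        OpticalProperties(1.0, 10.0, 1.5)
    props = OpticalProperties(1.0, 10.0, 0.9)
    assert props.mu_t == pytest.approx(11.0)
    assert props.mu_s_reduced == pytest.approx(1.0)
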