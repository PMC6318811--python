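"""Optical properties of pigmented skin, blood, and ICG-doped erythrocyte particles.

All coefficients are in mm^-1 and wavelengths in nm.  The skin model is a
layered epidermis (a melaninless layer over a thin melanosome-containing
basal layer) on a vascularised dermis.  Melanin content is parameterised by
the melanosome volume fraction ``fmel`` of the basal layer: 4%, 15% and 50%
for lightly, moderately and heavily pigmented skin.

Blood vessels may additionally contain NIR erythrocyte-derived transducers
(NETs) — erythrocyte-membrane vesicles loaded with indocyanine green (ICG).
Their effect on the effective vessel optical properties is a linear
volume-fraction mixture, and the ICG concentration in the fabrication
buffer needed to hit a target vessel absorption coefficient follows from an
empirical linear regression [ICG] = 17.8 * mu_a_NETs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "OpticalProperties",
    "PigmentationLevel",
    "DermisDepthBin",
    "NETFormulation",
    "PIGMENTATION_LEVELS",
    "DERMIS_DEPTH_BINS",
    "blood_properties",
    "mu_a_baseline",
    "mu_a_melanosome",
    "mu_a_basal",
    "mu_s_skin",
    "skin_anisotropy",
    "vessel_screening_factor",
    "mu_a_dermis_adjusted",
    "mu_a_dermis_oct",
    "vessel_effective_properties",
    "icg_for_target_mu_a",
    "DEFAULT_F_BLOOD",
    "ICG_SLOPE_UM_PER_MM1",
]

#: slope of the empirical ICG-concentration vs NET-absorption regression (uM per mm^-1)
ICG_SLOPE_UM_PER_MM1 = 17.8

#: blood volume fraction of healthy dermis used for imported (OCT-style) geometries
DEFAULT_F_BLOOD = 0.002


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption/scattering coefficients (mm^-1) and anisotropy of one material."""

    mu_a: float
    mu_s: float
    g: float

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s < 0:
            raise ValueError(f"mu_s must be >= 0, got {self.mu_s}")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError(f"anisotropy g must be in [-1, 1], got {self.g}")

    @property
    def mu_t(self) -> float:
        """Total attenuation coefficient mu_a + mu_s (mm^-1)."""
        return self.mu_a + self.mu_s

    @property
    def mu_s_reduced(self) -> float:
        """Reduced scattering coefficient mu_s * (1 - g) (mm^-1)."""
        return self.mu_s * (1.0 - self.g)


@dataclass(frozen=True)
class PigmentationLevel:
    """Melanosome volume fraction of the basal epidermal layer."""

    fmel: float
    label: str = "custom"

    def __post_init__(self) -> None:
        if not 0.0 <= self.fmel < 1.0:
            raise ValueError(f"fmel must be in [0, 1), got {self.fmel}")


#: named pigmentation levels (Fitzpatrick-type surrogates)
PIGMENTATION_LEVELS = {
    "light": PigmentationLevel(0.04, "light"),
    "moderate": PigmentationLevel(0.15, "moderate"),
    "heavy": PigmentationLevel(0.50, "heavy"),
}


@dataclass(frozen=True)
class DermisDepthBin:
    """Depth bin of the dermis with mean PWS vessel radius and blood volume fraction.

    Used to adjust the bulk dermal absorption coefficient for optical
    screening by the resident vascular plexus when single vessels are
    modelled explicitly.
    """

    z_min: float  # um below surface
    z_max: float  # um
    r_i: float  # mean vessel radius, um
    f_i: float  # fractional blood-vessel volume

    def __post_init__(self) -> None:
        if not self.z_min < self.z_max:
            raise ValueError("z_min must be < z_max")
        if self.r_i <= 0:
            raise ValueError("vessel radius must be positive")
        if not 0.0 <= self.f_i < 1.0:
            raise ValueError("blood volume fraction must be in [0, 1)")


#: depth-binned mean vessel radius / blood volume fraction of PWS dermis
DERMIS_DEPTH_BINS = (
    DermisDepthBin(60.0, 260.0, 25.0, 0.052),
    DermisDepthBin(260.0, 460.0, 37.0, 0.080),
    DermisDepthBin(460.0, 660.0, 34.0, 0.038),
    DermisDepthBin(660.0, 860.0, 27.0, 0.025),
    DermisDepthBin(860.0, 1060.0, 24.0, 0.020),
    DermisDepthBin(1060.0, 2000.0, 24.0, 0.015),
)

# NET formulation scattering properties at 755 nm by size class:
# micro (~4 um mean diameter, Mie regime, strongly forward scattering) and
# nano (~92 nm mean diameter).
_NET_SCATTERING = {
    "micro": (2.20, 0.99),
    "nano": (0.06, 0.55),
}


@dataclass(frozen=True)
class NETFormulation:
    """An erythrocyte-derived particle formulation inside a vessel.

    Parameters
    ----------
    kind : {"micro", "nano"}
        Particle size class; fixes the scattering coefficient and
        anisotropy (2.20 mm^-1 / 0.99 for micro, 0.06 mm^-1 / 0.55 for
        nano, both at 755 nm).
    f_nets : float
        Volume fraction of NETs within the vessel (0..1).
    mu_a_nets : float
        Absorption coefficient of the particles themselves (mm^-1),
        tunable through the ICG content of the fabrication buffer.
    """

    kind: str
    f_nets: float
    mu_a_nets: float

    def __post_init__(self) -> None:
        if self.kind not in _NET_SCATTERING:
            raise ValueError(f"kind must be one of {sorted(_NET_SCATTERING)}, got {self.kind!r}")
        if not 0.0 <= self.f_nets <= 1.0:
            raise ValueError("f_nets must be in [0, 1]")
        if self.mu_a_nets < 0:
            raise ValueError("mu_a_nets must be >= 0")

    @property
    def mu_s_nets(self) -> float:
        return _NET_SCATTERING[self.kind][0]

    @property
    def g_nets(self) -> float:
        return _NET_SCATTERING[self.kind][1]

    @property
    def icg_concentration(self) -> float:
        """ICG concentration in the fabrication buffer (uM) for this formulation."""
        return ICG_SLOPE_UM_PER_MM1 * self.mu_a_nets

    @classmethod
    def for_target_mu_a_bv(
        cls, kind: str, f_nets: float, target_mu_a_bv: float, wavelength: float = 755.0
    ) -> "NETFormulation":
        """Formulation whose vessel-level absorption equals ``target_mu_a_bv``."""
        blood = blood_properties(wavelength)
        if f_nets <= 0:
            raise ValueError("f_nets must be positive to reach a target vessel absorption")
        mu_a_nets = (target_mu_a_bv - (1.0 - f_nets) * blood.mu_a) / f_nets
        if mu_a_nets < 0:
            raise ValueError(
                f"target mu_a_BV={target_mu_a_bv} mm^-1 is below the minimum achievable "
                f"{(1.0 - f_nets) * blood.mu_a:.3f} mm^-1 at f_nets={f_nets}"
            )
        return cls(kind, f_nets, mu_a_nets)


# Blood optical properties at 45% hematocrit, 70% oxygen saturation; only the
# two treatment wavelengths are tabulated (no spectral interpolation).
_BLOOD = {
    585.0: OpticalProperties(17.91, 76.05, 0.970),
    755.0: OpticalProperties(0.44, 79.85, 0.983),
}

#: default skin scattering anisotropy at the two treatment wavelengths
_SKIN_G = {585.0: 0.80, 755.0: 0.91}


def blood_properties(wavelength: float) -> OpticalProperties:
    """Whole-blood optical properties (45% hct, 70% SO2) at 585 or 755 nm."""
    try:
        return _BLOOD[float(wavelength)]
    except KeyError:
        raise ValueError(
            f"blood properties tabulated only at {sorted(_BLOOD)} nm, got {wavelength}"
        ) from None


def skin_anisotropy(wavelength: float) -> float:
    """Scattering anisotropy of skin: 0.80 at 585 nm, 0.91 at 755 nm."""
    try:
        return _SKIN_G[float(wavelength)]
    except KeyError:
        raise ValueError(
            f"skin anisotropy tabulated only at {sorted(_SKIN_G)} nm, got {wavelength}"
        ) from None


def _check_wavelength(wavelength: float) -> float:
    wavelength = float(wavelength)
    if not 400.0 <= wavelength <= 1100.0:
        raise ValueError(f"wavelength must be in [400, 1100] nm, got {wavelength}")
    return wavelength


def mu_a_baseline(wavelength: float) -> float:
    """Baseline absorption of melaninless epidermis / bloodless dermis (mm^-1).

    mu_a,base = 0.0244 + 8.53 * exp(-(lambda - 154) / 66.2)
    """
    wavelength = _check_wavelength(wavelength)
    return 0.0244 + 8.53 * math.exp(-(wavelength - 154.0) / 66.2)


def mu_a_melanosome(wavelength: float) -> float:
    """Absorption coefficient of a single melanosome: 6.6e10 * lambda^-3.33 (mm^-1)."""
    wavelength = _check_wavelength(wavelength)
    return 6.6e10 * wavelength**-3.33


def mu_a_basal(wavelength: float, fmel: float) -> float:
    """Absorption of the basal epidermal layer: melanosome/baseline volume mixture."""
    if not 0.0 <= fmel <= 1.0:
        raise ValueError(f"fmel must be in [0, 1], got {fmel}")
    return fmel * mu_a_melanosome(wavelength) + (1.0 - fmel) * mu_a_baseline(wavelength)


def mu_s_skin(wavelength: float, g: float | None = None) -> float:
    """Scattering coefficient of skin layers (mm^-1).

    mu_s = (2e4 * lambda^-1.5 + 2e11 * lambda^-4) / (1 - g)

    The numerator is the reduced scattering coefficient (Mie + Rayleigh
    power laws); division by (1 - g) converts to mu_s.  ``g`` defaults to
    the tabulated skin anisotropy at the given wavelength.
    """
    wavelength = _check_wavelength(wavelength)
    if g is None:
        g = skin_anisotropy(wavelength)
    if g >= 1.0:
        raise ValueError("anisotropy g must be < 1 (mu_s diverges as g -> 1)")
    mu_s_prime = 2e4 * wavelength**-1.5 + 2e11 * wavelength**-4
    return mu_s_prime / (1.0 - g)


def vessel_screening_factor(mu_a_blood: float, r_i: float) -> float:
    """Optical screening correction C_i for a vessel of radius ``r_i``.

    C_i ~= 0.039 + 0.486 exp(-mu_a_blood r_i / 0.193) + 0.468 exp(-mu_a_blood r_i / 0.914)

    Unit convention: the printed constants reproduce the tabulated adjusted
    dermal absorption values when the product is formed with ``mu_a_blood``
    in mm^-1 and ``r_i`` in um; that convention is adopted here.
    """
    if mu_a_blood < 0:
        raise ValueError("mu_a_blood must be >= 0")
    if r_i <= 0:
        raise ValueError("r_i must be > 0")
    x = mu_a_blood * r_i
    return 0.039 + 0.486 * math.exp(-x / 0.193) + 0.468 * math.exp(-x / 0.914)


def mu_a_dermis_adjusted(
    wavelength: float, depth_bin: DermisDepthBin, blood: OpticalProperties | None = None
) -> float:
    """Dermal absorption adjusted for screening by the PWS plexus in one depth bin.

    mu_a,der = f_i * C_i * mu_a,blood + (1 - f_i) * mu_a,base
    """
    if blood is None:
        blood = blood_properties(wavelength)
    c_i = vessel_screening_factor(blood.mu_a, depth_bin.r_i)
    return depth_bin.f_i * c_i * blood.mu_a + (1.0 - depth_bin.f_i) * mu_a_baseline(wavelength)


def mu_a_dermis_oct(
    wavelength: float,
    f_blood: float = DEFAULT_F_BLOOD,
    blood: OpticalProperties | None = None,
) -> float:
    """Dermal absorption for imported vessel geometries: plain blood/baseline mixture.

    Used when the vascular plexus is represented explicitly (e.g. from an
    OCT-derived mask), so no screening correction is applied; ``f_blood``
    is the blood volume fraction of the healthy dermis (default 0.2%).
    """
    if not 0.0 <= f_blood <= 1.0:
        raise ValueError(f"f_blood must be in [0, 1], got {f_blood}")
    if blood is None:
        blood = blood_properties(wavelength)
    return f_blood * blood.mu_a + (1.0 - f_blood) * mu_a_baseline(wavelength)


def vessel_effective_properties(
    blood: OpticalProperties, net: NETFormulation | None
) -> OpticalProperties:
    """Effective optical properties of a vessel containing blood and (optionally) NETs.

    Each of mu_a, mu_s, g mixes linearly by volume fraction:
    mu_a,BV = (1 - f) mu_a,blood + f mu_a,NETs  (and likewise for mu_s, g).
    """
    if net is None:
        return blood
    f = net.f_nets
    mu_a = (1.0 - f) * blood.mu_a + f * net.mu_a_nets
    mu_s = (1.0 - f) * blood.mu_s + f * net.mu_s_nets
    g = (1.0 - f) * blood.g + f * net.g_nets
    return OpticalProperties(mu_a, mu_s, g)


def icg_for_target_mu_a(
    target_mu_a_bv: float, f_nets: float, mu_a_blood: float
) -> float:
    """ICG fabrication-buffer concentration (uM) for a target vessel absorption.

    [ICG] = 17.8 * (mu_a,BV - (1 - f_NETs) mu_a,blood) / f_NETs

    Raises
    ------
    ValueError
        If the target is below (1 - f_NETs) * mu_a_blood, the absorption of
        the NET-free blood fraction, which no ICG loading can undercut.
    """
    if not 0.0 < f_nets <= 1.0:
        raise ValueError(f"f_nets must be in (0, 1], got {f_nets}")
    if mu_a_blood < 0:
        raise ValueError("mu_a_blood must be >= 0")
    minimum = (1.0 - f_nets) * mu_a_blood
    if target_mu_a_bv < minimum:
        raise ValueError(
            f"target mu_a_BV={target_mu_a_bv} mm^-1 infeasible: minimum achievable is "
            f"{minimum:.3f} mm^-1 at f_nets={f_nets} (blood alone)"
        )
    return ICG_SLOPE_UM_PER_MM1 * (target_mu_a_bv - minimum) / f_nets
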