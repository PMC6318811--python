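"""Synthetic inputs with the statistical structure the pipeline assumes.

The patient vasculature in the source study was a 5 x 5 x 2.8 mm OCT
volume that is not publicly available.  :func:`make_plexus_volume`
emulates its relevant statistics — a plexus of near-y-oriented tubes with
diameters in the 60–650 um range (most around 200 um) at depths up to
1 mm — together with the acquisition artifacts the preprocessing chain is
designed to remove: multiplicative speckle and an additive slow scan-line
drift that is uniform along x.  The generator returns both the noisy
intensity volume and the clean ground-truth mask, so every preprocessing
stage can be scored against truth.

:func:`make_single_vessel_case` builds the canonical layered-skin
single-vessel scenario used throughout the dosimetry results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from pwstherm.geometry import TissueModel, CylVessel, build_layered_model
from pwstherm.oct import IntensityVolume
from pwstherm.optics import NETFormulation, PigmentationLevel, PIGMENTATION_LEVELS

__all__ = [
    "PlexusParams",
    "make_plexus_volume",
    "make_single_vessel_case",
]


@dataclass
class PlexusParams:
    """Ground-truth parameters of a generated plexus volume."""

    extent_um: tuple[float, float, float]  # (x, y, z)
    pitch_um: float
    n_vessels: int
    diameters_um: list[float] = field(default_factory=list)
    depths_um: list[float] = field(default_factory=list)
    tilts_deg: list[float] = field(default_factory=list)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=list)


def make_plexus_volume(
    extent_um: tuple[float, float, float] = (2000.0, 2000.0, 1400.0),
    pitch_um: float = 10.0,
    n_vessels: int = 12,
    diameter_range_um: tuple[float, float] = (60.0, 650.0),
    diameter_mode_um: float = 200.0,
    depth_max_um: float = 1000.0,
    oblique_fraction: float = 0.2,
    max_tilt_deg: float = 5.0,
    speckle_shape: float = 10.0,
    drift_amplitude: float = 0.3,
    background: float = 0.05,
    psf_sigma_voxels: float = 1.0,
    seed: int = 0,
) -> tuple[IntensityVolume, np.ndarray, PlexusParams]:
    """Generate a noisy OCT-like volume and its ground-truth vessel mask.

    Vessels are straight tubes spanning the full y-extent; a configurable
    fraction is tilted in the x–y plane by up to ``max_tilt_deg``.
    Diameters are log-normal with mode ``diameter_mode_um``, clipped to
    ``diameter_range_um``; vessel-centre depths are uniform between the
    shallowest admissible depth and ``depth_max_um``.  Intensity = mask
    convolved with a small Gaussian PSF, plus background, times
    gamma-distributed multiplicative speckle, plus an additive slow drift
    that is uniform along x (the motion-artifact surrogate).  Vessels that
    would exit the volume are clipped at its faces.  Bit-reproducible
    under ``seed``.

    The default speckle shape of 10 (relative std ~0.32) models an
    angiography volume after modest frame averaging — speckle contrast
    1/sqrt(N) for N ~ 10 frames — which keeps the vessel/background
    intensity classes separable, the regime a global-threshold
    segmentation chain assumes.
    """
    rng = np.random.default_rng(seed)
    ex, ey, ez = extent_um
    nx = int(round(ex / pitch_um))
    ny = int(round(ey / pitch_um))
    nz = int(round(ez / pitch_um))
    mask = np.zeros((nz, ny, nx), dtype=bool)
    params = PlexusParams(
        extent_um=tuple(extent_um),
        pitch_um=pitch_um,
        n_vessels=n_vessels,
        seed=seed,
    )

    x = (np.arange(nx) + 0.5) * pitch_um
    z = (np.arange(nz) + 0.5) * pitch_um
    y = (np.arange(ny) + 0.5) * pitch_um
    zz, xx = np.meshgrid(z, x, indexing="ij")  # (nz, nx)

    lo, hi = diameter_range_um
    sigma = 0.45
    for _ in range(n_vessels):
        d = float(np.clip(rng.lognormal(np.log(diameter_mode_um), sigma), lo, hi))
        r = d / 2.0
        z0 = float(rng.uniform(min(r + pitch_um, depth_max_um), depth_max_um))
        x0 = float(rng.uniform(0.15 * ex, 0.85 * ex))
        tilt = 0.0
        if rng.uniform() < oblique_fraction:
            tilt = float(rng.uniform(-max_tilt_deg, max_tilt_deg))
        params.diameters_um.append(d)
        params.depths_um.append(z0)
        params.tilts_deg.append(tilt)
        slope = np.tan(np.deg2rad(tilt))
        cx = x0 + slope * (y - ey / 2.0)  # centre x per y slice
        for j in range(ny):
            mask[:, j, :] |= (xx - cx[j]) ** 2 + (zz - z0) ** 2 <= r**2

    signal = ndimage.gaussian_filter(mask.astype(float), psf_sigma_voxels)
    intensity = background + signal
    if speckle_shape > 0:
        speckle = rng.gamma(speckle_shape, 1.0 / speckle_shape, size=intensity.shape)
        intensity = intensity * speckle
    if drift_amplitude > 0:
        # slow drift: smooth in y and z, uniform along x
        drift = rng.standard_normal((nz, ny))
        drift = ndimage.gaussian_filter(drift, (nz / 6.0, ny / 6.0))
        drift -= drift.min()
        if drift.max() > 0:
            drift /= drift.max()
        intensity = intensity + drift_amplitude * drift[:, :, np.newaxis]
    intensity = np.clip(intensity, 0.0, None)

    volume = IntensityVolume(voxels=intensity, dx=pitch_um, dy=pitch_um, dz=pitch_um)
    return volume, mask, params


def _resolve_pigmentation(pigmentation: str | PigmentationLevel) -> PigmentationLevel:
    if isinstance(pigmentation, str):
        try:
            return PIGMENTATION_LEVELS[pigmentation]
        except KeyError:
            raise ValueError(
                f"unknown pigmentation {pigmentation!r}; expected one of "
                f"{sorted(PIGMENTATION_LEVELS)}"
            ) from None
    return pigmentation


def make_single_vessel_case(
    depth_um: float = 500.0,
    diameter_um: float = 200.0,
    pigmentation: str | PigmentationLevel = "light",
    net: NETFormulation | None = None,
    wavelength: float = 585.0,
    width_x_um: float = 12000.0,
    depth_z_um: float = 4000.0,
    dx_um: float = 10.0,
    dz_um: float = 5.0,
    use_adjusted_dermis: bool = True,
) -> TissueModel:
    """Canonical single-vessel scenario: layered skin + one 200-um vessel.

    ``depth_um`` is the vessel-top depth below the surface (500 or 800 um
    in the reference scenarios).  The default domain carries generous
    optical padding — 3 mm laterally beyond the 6-mm beam and dermis
    extended to 4 mm depth — so that photons are not artificially lost at
    the box faces (real dermis/subcutis continues beyond the 2-mm tissue
    box of interest, and deposition there back-scatters into it); the
    thermal and damage stages crop back to the 2-mm box.
    """
    pig = _resolve_pigmentation(pigmentation)
    vessels = [CylVessel(top_depth=depth_um, diameter=diameter_um)] if diameter_um else []
    return build_layered_model(
        width_x=width_x_um,
        depth_z=depth_z_um,
        dx=dx_um,
        dz=dz_um,
        pigmentation=pig,
        vessels=vessels,
        wavelength=wavelength,
        use_adjusted_dermis=use_adjusted_dermis,
        net=net,
    )
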