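"""Image-processing chain turning an OCT-like intensity volume into a vessel mask.

Three steps, applied in order:

1. motion-artifact removal — a hard-edged separable frequency mask applied
   to the 2-D Fourier transform of each en-face (x–y) section, retaining
   horizontal normalized frequencies in [0.1, 1.0] (1.0 = Nyquist) and
   vertical normalized frequencies in [0.0, 0.01];
2. thresholding to a binary mask (user-supplied global threshold or Otsu);
3. speckle removal with a 3-D median filter (default 3x3x3 window).

Volumes are ``(z, y, x)`` arrays; sections are x–y planes, "horizontal"
defaulting to the x axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "IntensityVolume",
    "remove_motion_artifact",
    "remove_motion_artifact_volume",
    "binarize",
    "despeckle",
    "preprocess_volume",
    "DEFAULT_HORIZONTAL_BAND",
    "DEFAULT_VERTICAL_BAND",
]

DEFAULT_HORIZONTAL_BAND = (0.1, 1.0)
DEFAULT_VERTICAL_BAND = (0.0, 0.01)


@dataclass
class IntensityVolume:
    """Scalar intensity volume with voxel pitch, axes ordered (z, y, x)."""

    voxels: np.ndarray
    dx: float  # um
    dy: float  # um
    dz: float  # um

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("intensity volume must be 3-D (z, y, x)")
        if not np.isfinite(self.voxels).all():
            raise ValueError("intensities must be finite")
        if (self.voxels < 0).any():
            raise ValueError("intensities must be non-negative")


def _band_mask(n: int, band: tuple[float, float]) -> np.ndarray:
    """Boolean pass mask over FFT bins for |f|/f_Nyquist within ``band``."""
    f_norm = np.abs(np.fft.fftfreq(n)) / 0.5
    lo, hi = band
    return (f_norm >= lo - 1e-12) & (f_norm <= hi + 1e-12)


def remove_motion_artifact(
    section: np.ndarray,
    horizontal_band: tuple[float, float] = DEFAULT_HORIZONTAL_BAND,
    vertical_band: tuple[float, float] = DEFAULT_VERTICAL_BAND,
    horizontal_axis: int = 1,
) -> np.ndarray:
    """Separable hard-edged frequency mask on one 2-D (y, x) section.

    Slowly varying structures that are uniform along the horizontal axis
    (scan-line drift) fall below the 0.1 horizontal cutoff and are
    removed; structures coherent along the vertical axis pass the [0,
    0.01] vertical band.  Returns the real part of the inverse transform.
    """
    section = np.asarray(section, dtype=float)
    if section.ndim != 2:
        raise ValueError("motion-artifact removal expects a 2-D section")
    vertical_axis = 1 - horizontal_axis
    mask_h = _band_mask(section.shape[horizontal_axis], horizontal_band)
    mask_v = _band_mask(section.shape[vertical_axis], vertical_band)
    if horizontal_axis == 1:
        mask2d = np.outer(mask_v, mask_h)
    else:
        mask2d = np.outer(mask_h, mask_v)
    spec = np.fft.fft2(section)
    return np.real(np.fft.ifft2(spec * mask2d))


def remove_motion_artifact_volume(
    volume: IntensityVolume | np.ndarray,
    horizontal_band: tuple[float, float] = DEFAULT_HORIZONTAL_BAND,
    vertical_band: tuple[float, float] = DEFAULT_VERTICAL_BAND,
    horizontal_axis: int = 1,
) -> np.ndarray:
    """Apply :func:`remove_motion_artifact` to every en-face (x–y) section."""
    vox = volume.voxels if isinstance(volume, IntensityVolume) else np.asarray(volume, float)
    out = np.empty_like(vox)
    for k in range(vox.shape[0]):
        out[k] = remove_motion_artifact(vox[k], horizontal_band, vertical_band, horizontal_axis)
    return out


def binarize(volume: np.ndarray, threshold: float | str = "otsu") -> np.ndarray:
    """Threshold an intensity volume: voxels strictly above threshold are vessel."""
    vox = volume.voxels if isinstance(volume, IntensityVolume) else np.asarray(volume, float)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        from skimage.filters import threshold_otsu

        # flatten: the threshold depends only on the histogram, and 3-D
        # shapes trip skimage's RGB-image heuristic warning
        threshold = threshold_otsu(vox.ravel())
    return vox > float(threshold)


def despeckle(mask: np.ndarray, window: int | tuple[int, int, int] = 3) -> np.ndarray:
    """3-D median filter on a binary mask (odd window per axis, default 3^3)."""
    mask = np.asarray(mask)
    sizes = (window,) * 3 if np.isscalar(window) else tuple(window)
    if any(s % 2 == 0 or s < 1 for s in sizes):
        raise ValueError("median window must be odd and positive per axis")
    return ndimage.median_filter(mask.astype(np.uint8), size=sizes).astype(bool)


def preprocess_volume(
    volume: IntensityVolume | np.ndarray,
    threshold: float | str = "otsu",
    horizontal_band: tuple[float, float] = DEFAULT_HORIZONTAL_BAND,
    vertical_band: tuple[float, float] = DEFAULT_VERTICAL_BAND,
    horizontal_axis: int = 1,
    window: int | tuple[int, int, int] = 3,
) -> np.ndarray:
    """Full chain: artifact removal -> thresholding -> 3-D median despeckle."""
    filtered = remove_motion_artifact_volume(
        volume, horizontal_band, vertical_band, horizontal_axis
    )
    return despeckle(binarize(filtered, threshold), window)
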