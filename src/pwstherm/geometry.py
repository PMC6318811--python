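"""Voxelized tissue models of port-wine-stain skin.

Coordinate convention: ``z`` increases downward from the skin surface
(z = 0); voxel ``k`` occupies the half-open interval [k*dz, (k+1)*dz).
``x = 0`` lies at the beam centre of a laterally symmetric domain.  Label
maps are 2-D ``(nz, nx)`` cross-sections for y-invariant geometries
(vessels run the full y-extent) or 3-D ``(nz, ny, nx)`` volumes for
imported vessel masks.

Labels: 1 = melaninless epidermis, 2 = melanosome-containing basal layer,
3 = dermis, 4 = blood vessel.  Air above the surface is not gridded; the
surface boundary is handled by the transport and heat solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from pwstherm.optics import (
    DERMIS_DEPTH_BINS,
    NETFormulation,
    OpticalProperties,
    PigmentationLevel,
    blood_properties,
    mu_a_baseline,
    mu_a_basal,
    mu_a_dermis_adjusted,
    mu_a_dermis_oct,
    mu_s_skin,
    skin_anisotropy,
    vessel_effective_properties,
)

__all__ = [
    "LABEL_EPIDERMIS",
    "LABEL_BASAL",
    "LABEL_DERMIS",
    "LABEL_VESSEL",
    "ThermalProperties",
    "THERMAL_BY_LABEL",
    "CylVessel",
    "TissueModel",
    "build_layered_model",
    "import_vessel_mask",
]

LABEL_EPIDERMIS = 1
LABEL_BASAL = 2
LABEL_DERMIS = 3
LABEL_VESSEL = 4

#: nominal layer thicknesses (um)
EPIDERMIS_THICKNESS = 45.0
BASAL_THICKNESS = 15.0
EPIDERMIS_TOTAL = EPIDERMIS_THICKNESS + BASAL_THICKNESS


@dataclass(frozen=True)
class ThermalProperties:
    """Density (kg m^-3), specific heat (J kg^-1 C^-1), conductivity (W m^-1 C^-1)."""

    rho: float
    c: float
    kappa: float


# All tissues share density and specific heat; conductivity differs: the
# (relatively dry) epidermis conducts about half as well as dermis/blood.
THERMAL_BY_LABEL = {
    LABEL_EPIDERMIS: ThermalProperties(1200.0, 3600.0, 0.26),
    LABEL_BASAL: ThermalProperties(1200.0, 3600.0, 0.26),
    LABEL_DERMIS: ThermalProperties(1200.0, 3600.0, 0.53),
    LABEL_VESSEL: ThermalProperties(1200.0, 3600.0, 0.53),
}


@dataclass(frozen=True)
class CylVessel:
    """Cylindrical vessel running parallel to the y-axis.

    ``top_depth`` is the z of the vessel top below the surface (um);
    ``x_center`` its lateral position relative to the beam centre (um).
    """

    top_depth: float
    diameter: float
    x_center: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("vessel diameter must be positive")
        if self.top_depth < EPIDERMIS_TOTAL:
            raise ValueError(
                f"vessel top at {self.top_depth} um lies inside the epidermis "
                f"(< {EPIDERMIS_TOTAL} um)"
            )


@dataclass
class TissueModel:
    """Voxelized label map with per-label optical and thermal properties.

    ``labels`` is ``(nz, nx)`` for y-invariant models or ``(nz, ny, nx)``
    for full 3-D models.  ``dermis_mu_a_by_row`` optionally carries a
    depth-dependent dermal absorption coefficient (one value per z row),
    used when the resident vascular plexus is modelled through a
    screening-adjusted bulk absorption rather than explicit vessels.
    """

    labels: np.ndarray
    dx: float  # um
    dz: float  # um
    dy: float | None = None  # um; None for y-invariant 2-D models
    wavelength: float = 585.0
    optical_by_label: dict[int, OpticalProperties] = field(default_factory=dict)
    dermis_mu_a_by_row: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim not in (2, 3):
            raise ValueError("labels must be a 2-D (nz, nx) or 3-D (nz, ny, nx) array")
        if self.labels.ndim == 3 and self.dy is None:
            raise ValueError("3-D label maps require a y pitch dy")
        if self.dermis_mu_a_by_row is not None:
            self.dermis_mu_a_by_row = np.asarray(self.dermis_mu_a_by_row, dtype=float)
            if self.dermis_mu_a_by_row.shape != (self.labels.shape[0],):
                raise ValueError("dermis_mu_a_by_row must have one entry per z row")

    # -- grid helpers ------------------------------------------------------

    @property
    def is_2d(self) -> bool:
        return self.labels.ndim == 2

    @property
    def nz(self) -> int:
        return self.labels.shape[0]

    @property
    def nx(self) -> int:
        return self.labels.shape[-1]

    @property
    def ny(self) -> int:
        return 1 if self.is_2d else self.labels.shape[1]

    @property
    def depth(self) -> float:
        """Physical depth of the gridded domain (um)."""
        return self.nz * self.dz

    @property
    def width_x(self) -> float:
        return self.nx * self.dx

    def z_centers(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.dz

    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx - self.width_x / 2.0

    # -- masks -------------------------------------------------------------

    def vessel_mask(self) -> np.ndarray:
        return self.labels == LABEL_VESSEL

    def epidermis_mask(self) -> np.ndarray:
        return (self.labels == LABEL_EPIDERMIS) | (self.labels == LABEL_BASAL)

    # -- property grids ----------------------------------------------------

    def optical_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-voxel (mu_a, mu_s, g) arrays in mm^-1 / dimensionless.

        Dermis absorption may vary with depth (``dermis_mu_a_by_row``);
        all other properties are uniform per label.
        """
        shape = self.labels.shape
        mu_a = np.zeros(shape, dtype=np.float64)
        mu_s = np.zeros(shape, dtype=np.float64)
        g = np.zeros(shape, dtype=np.float64)
        for label, props in self.optical_by_label.items():
            sel = self.labels == label
            mu_a[sel] = props.mu_a
            mu_s[sel] = props.mu_s
            g[sel] = props.g
        if self.dermis_mu_a_by_row is not None:
            dermis = self.labels == LABEL_DERMIS
            rows = self.dermis_mu_a_by_row.reshape((-1,) + (1,) * (self.labels.ndim - 1))
            mu_a = np.where(dermis, np.broadcast_to(rows, shape), mu_a)
        return mu_a, mu_s, g

    def thermal_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-voxel (kappa, rho, C) arrays (SI units)."""
        shape = self.labels.shape
        kappa = np.zeros(shape, dtype=np.float64)
        rho = np.zeros(shape, dtype=np.float64)
        c = np.zeros(shape, dtype=np.float64)
        for label, props in THERMAL_BY_LABEL.items():
            sel = self.labels == label
            kappa[sel] = props.kappa
            rho[sel] = props.rho
            c[sel] = props.c
        return kappa, rho, c

    # -- views -------------------------------------------------------------

    def crop(
        self, half_width_um: float | None = None, depth_um: float | None = None
    ) -> "TissueModel":
        """Central-x and/or top-z crop of the model.

        Used to hand the thermal solver the tissue box of interest when
        the transport grid carries extra optical padding.
        """
        keep_x = (
            np.abs(self.x_centers()) <= half_width_um
            if half_width_um is not None
            else np.ones(self.nx, dtype=bool)
        )
        if not keep_x.any():
            raise ValueError("crop window excludes every column")
        nz_keep = self.nz if depth_um is None else int(round(depth_um / self.dz))
        labels = self.labels[:nz_keep, ..., keep_x]
        rows = self.dermis_mu_a_by_row
        return TissueModel(
            labels=labels,
            dx=self.dx,
            dz=self.dz,
            dy=self.dy,
            wavelength=self.wavelength,
            optical_by_label=dict(self.optical_by_label),
            dermis_mu_a_by_row=None if rows is None else rows[:nz_keep].copy(),
            meta=dict(self.meta),
        )

    def crop_x(self, half_width: float) -> "TissueModel":
        """Central-x crop of the model (used to shrink the thermal domain)."""
        return self.crop(half_width_um=half_width)

    def central_slab_2d(self) -> "TissueModel":
        """Central x–z cross-section of a 3-D model as a 2-D model."""
        if self.is_2d:
            return self
        labels = self.labels[:, self.ny // 2, :]
        return TissueModel(
            labels=labels,
            dx=self.dx,
            dz=self.dz,
            dy=None,
            wavelength=self.wavelength,
            optical_by_label=dict(self.optical_by_label),
            dermis_mu_a_by_row=None
            if self.dermis_mu_a_by_row is None
            else self.dermis_mu_a_by_row.copy(),
            meta=dict(self.meta),
        )

    # -- IO ----------------------------------------------------------------

    def to_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            ds = f.create_dataset("labels", data=self.labels, compression="gzip")
            ds.attrs["axis_order"] = "zx" if self.is_2d else "zyx"
            f.attrs["dx_um"] = self.dx
            f.attrs["dz_um"] = self.dz
            if self.dy is not None:
                f.attrs["dy_um"] = self.dy
            f.attrs["wavelength_nm"] = self.wavelength
            if self.dermis_mu_a_by_row is not None:
                f.create_dataset("dermis_mu_a_by_row", data=self.dermis_mu_a_by_row)
            grp = f.create_group("optical_by_label")
            for label, props in self.optical_by_label.items():
                grp.attrs[str(label)] = (props.mu_a, props.mu_s, props.g)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "TissueModel":
        import h5py

        with h5py.File(path, "r") as f:
            labels = f["labels"][...]
            optical = {
                int(k): OpticalProperties(*map(float, v))
                for k, v in f["optical_by_label"].attrs.items()
            }
            dermis_rows = (
                f["dermis_mu_a_by_row"][...] if "dermis_mu_a_by_row" in f else None
            )
            return cls(
                labels=labels,
                dx=float(f.attrs["dx_um"]),
                dz=float(f.attrs["dz_um"]),
                dy=float(f.attrs["dy_um"]) if "dy_um" in f.attrs else None,
                wavelength=float(f.attrs["wavelength_nm"]),
                optical_by_label=optical,
                dermis_mu_a_by_row=dermis_rows,
            )

    def labels_to_tiff(self, path: str | Path) -> None:
        """Write the label map as a multi-page TIFF (one page per z slice)."""
        import tifffile

        data = self.labels if not self.is_2d else self.labels[:, np.newaxis, :]
        tifffile.imwrite(path, data.astype(np.uint8), metadata={"axes": "ZYX"})

    def materials_manifest(self):
        """DataFrame mapping labels to material names and optical properties."""
        import pandas as pd

        names = {
            LABEL_EPIDERMIS: "melaninless epidermis",
            LABEL_BASAL: "basal layer",
            LABEL_DERMIS: "dermis",
            LABEL_VESSEL: "vessel",
        }
        rows = []
        for label, props in sorted(self.optical_by_label.items()):
            rows.append(
                {
                    "label": label,
                    "material": names.get(label, f"label {label}"),
                    "mu_a_mm^-1": props.mu_a,
                    "mu_s_mm^-1": props.mu_s,
                    "g": props.g,
                }
            )
        return pd.DataFrame(rows)


def _snap_layer_rows(dz: float) -> tuple[int, int]:
    """Rows for the melaninless and basal layers, snapped to the voxel grid."""
    n_epi = max(1, int(round(EPIDERMIS_THICKNESS / dz)))
    n_basal = max(1, int(round(BASAL_THICKNESS / dz)))
    return n_epi, n_basal


def _optical_table(
    wavelength: float,
    pigmentation: PigmentationLevel,
    net: NETFormulation | None,
    dermis_mu_a: float,
) -> dict[int, OpticalProperties]:
    g = skin_anisotropy(wavelength)
    mu_s = mu_s_skin(wavelength, g)
    blood = blood_properties(wavelength)
    return {
        LABEL_EPIDERMIS: OpticalProperties(mu_a_baseline(wavelength), mu_s, g),
        LABEL_BASAL: OpticalProperties(mu_a_basal(wavelength, pigmentation.fmel), mu_s, g),
        LABEL_DERMIS: OpticalProperties(dermis_mu_a, mu_s, g),
        LABEL_VESSEL: vessel_effective_properties(blood, net),
    }


def _adjusted_dermis_rows(z_centers: np.ndarray, wavelength: float) -> np.ndarray:
    """Depth-binned screening-adjusted dermal absorption, one value per z row."""
    blood = blood_properties(wavelength)
    out = np.full(z_centers.shape, mu_a_baseline(wavelength))
    for b in DERMIS_DEPTH_BINS:
        sel = (z_centers >= b.z_min) & (z_centers < b.z_max)
        out[sel] = mu_a_dermis_adjusted(wavelength, b, blood)
    # below the last tabulated bin, extend its value
    last = DERMIS_DEPTH_BINS[-1]
    out[z_centers >= last.z_max] = mu_a_dermis_adjusted(wavelength, last, blood)
    return out


def build_layered_model(
    width_x: float,
    depth_z: float,
    dx: float,
    dz: float,
    pigmentation: PigmentationLevel,
    vessels: Sequence[CylVessel] = (),
    wavelength: float = 585.0,
    use_adjusted_dermis: bool = True,
    net: NETFormulation | None = None,
) -> TissueModel:
    """Layered skin cross-section with optional cylindrical vessels.

    The epidermis is a 45-um melaninless layer over a 15-um basal layer
    (snapped to whole voxels); the dermis fills the rest of ``depth_z``.
    With ``use_adjusted_dermis`` the dermal absorption is depth-binned and
    screening-corrected for the unresolved PWS plexus; otherwise the
    healthy-dermis blood/baseline mixture is used.

    Vessels are y-parallel cylinders labelled by voxel-centre membership.
    """
    nx = int(round(width_x / dx))
    nz = int(round(depth_z / dz))
    labels = np.full((nz, nx), LABEL_DERMIS, dtype=np.int8)
    n_epi, n_basal = _snap_layer_rows(dz)
    labels[:n_epi, :] = LABEL_EPIDERMIS
    labels[n_epi : n_epi + n_basal, :] = LABEL_BASAL

    z = (np.arange(nz) + 0.5) * dz
    x = (np.arange(nx) + 0.5) * dx - width_x / 2.0
    for v in vessels:
        if v.top_depth + v.diameter > depth_z:
            raise ValueError(
                f"vessel (top {v.top_depth} um, diameter {v.diameter} um) extends "
                f"below the {depth_z}-um domain"
            )
        r = v.diameter / 2.0
        zc = v.top_depth + r
        inside = (x[np.newaxis, :] - v.x_center) ** 2 + (z[:, np.newaxis] - zc) ** 2 <= r**2
        labels[inside] = LABEL_VESSEL

    if use_adjusted_dermis:
        dermis_rows = _adjusted_dermis_rows(z, wavelength)
        dermis_scalar = float(dermis_rows[min(nz - 1, n_epi + n_basal)])
    else:
        dermis_rows = None
        dermis_scalar = mu_a_dermis_oct(wavelength)

    optical = _optical_table(wavelength, pigmentation, net, dermis_scalar)
    return TissueModel(
        labels=labels,
        dx=dx,
        dz=dz,
        dy=None,
        wavelength=wavelength,
        optical_by_label=optical,
        dermis_mu_a_by_row=dermis_rows,
        meta={
            "pigmentation": pigmentation.label,
            "fmel": pigmentation.fmel,
            "epidermis_rows": n_epi,
            "basal_rows": n_basal,
            "use_adjusted_dermis": use_adjusted_dermis,
        },
    )


def import_vessel_mask(
    mask: np.ndarray,
    dx: float,
    dy: float,
    dz: float,
    pigmentation: PigmentationLevel,
    wavelength: float = 585.0,
    net: NETFormulation | None = None,
) -> TissueModel:
    """Build a 3-D tissue model from a binary vessel mask (axes z, y, x).

    A 60-um epidermis (45-um melaninless + 15-um basal, snapped to whole
    voxels) is prepended above the mask volume; mask voxels become vessel,
    everything else dermis with the healthy-dermis absorption mixture
    (explicit vessels make the screening adjustment unnecessary).
    """
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError("vessel mask must be a 3-D (z, y, x) array")
    if not all(p and p > 0 for p in (dx, dy, dz)):
        raise ValueError("voxel pitch (dx, dy, dz) must be positive")
    mask = mask.astype(bool)

    n_epi, n_basal = _snap_layer_rows(dz)
    nz_mask, ny, nx = mask.shape
    nz = n_epi + n_basal + nz_mask
    labels = np.full((nz, ny, nx), LABEL_DERMIS, dtype=np.int8)
    labels[:n_epi] = LABEL_EPIDERMIS
    labels[n_epi : n_epi + n_basal] = LABEL_BASAL
    body = labels[n_epi + n_basal :]
    body[mask] = LABEL_VESSEL

    optical = _optical_table(wavelength, pigmentation, net, mu_a_dermis_oct(wavelength))
    return TissueModel(
        labels=labels,
        dx=dx,
        dz=dz,
        dy=dy,
        wavelength=wavelength,
        optical_by_label=optical,
        dermis_mu_a_by_row=None,
        meta={
            "pigmentation": pigmentation.label,
            "fmel": pigmentation.fmel,
            "epidermis_rows": n_epi,
            "basal_rows": n_basal,
            "imported_mask": True,
        },
    )
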