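"""Monte Carlo photon transport in voxelized tissue.

Weighted-photon (implicit capture) Monte Carlo with Henyey–Greenstein
scattering and Russian-roulette termination, scoring the energy deposited
per voxel per unit incident energy.  Two source/scoring modes:

* **y-invariant** (2-D label maps): the flat-top disk beam is modelled as
  an infinite strip of the same width; photons launch at y = 0 and
  deposition is scored on the x–z grid (implicitly summed over y).  Near
  the beam axis — where all scored structure lies — strip and disk agree
  because the transport mean free path is far smaller than the beam
  radius.
* **full 3-D** (imported vessel-mask models): flat-top disk beam, 3-D
  scoring grid; a central x–z slab can be extracted for the 2-D thermal
  solve.

The skin surface is an air/tissue refractive boundary (n = 1.37 vs 1.0 by
default): the incident beam loses the normal-incidence specular fraction,
and photons reaching the surface from below undergo Fresnel/total internal
reflection.  Internal tissue boundaries are index-matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from pwstherm.geometry import TissueModel

__all__ = [
    "Beam",
    "SourceGrid",
    "RunStats",
    "run_mc",
    "source_to_power_density",
]

#: Russian-roulette weight threshold and survival probability
ROULETTE_WEIGHT = 1e-4
ROULETTE_SURVIVE = 0.1

DEFAULT_TISSUE_INDEX = 1.37


@dataclass(frozen=True)
class Beam:
    """Flat-top laser beam at normal incidence.

    ``radiant_exposure`` is the incident dosage D in J/cm^2;
    ``pulse_duration`` the pulse length in seconds (3 ms default).
    """

    wavelength: float
    diameter_mm: float = 6.0
    radiant_exposure: float = 1.0
    pulse_duration: float = 3e-3

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("beam diameter must be positive")
        if self.radiant_exposure <= 0:
            raise ValueError("radiant exposure must be positive")
        if self.pulse_duration <= 0:
            raise ValueError("pulse duration must be positive")


@dataclass
class RunStats:
    """Weight bookkeeping of one Monte Carlo run (fractions of launched weight)."""

    n_photons: int
    seed: int
    specular_reflected: float
    diffuse_reflected: float
    transmitted: float
    escaped_lateral: float
    absorbed: float
    roulette_net: float

    @property
    def reflected(self) -> float:
        return self.specular_reflected + self.diffuse_reflected

    @property
    def total(self) -> float:
        """Should equal 1 up to roulette variance (exact including roulette_net)."""
        return (
            self.reflected
            + self.transmitted
            + self.escaped_lateral
            + self.absorbed
            + self.roulette_net
        )


@dataclass
class SourceGrid:
    """Energy deposition per voxel per unit incident energy.

    ``S`` has the shape of the tissue model's label map.  For y-invariant
    (2-D) runs one unit of incident energy means the energy a strip beam
    delivers per unit y-length; for 3-D runs it is the total beam energy.
    """

    S: np.ndarray
    model: TissueModel = field(repr=False)
    beam: Beam
    stats: RunStats

    def central_slab(self, half_width_um: float | None = None) -> np.ndarray:
        """Average the 3-D deposition over a central y slab, as an (nz, nx) map.

        Returns deposition per voxel of the slab-averaged x–z grid,
        normalized so that the 2-D thermal solve sees the local volumetric
        density near y = 0 (fraction per (dz, dx, dy_slab=full slab)).
        """
        if self.S.ndim == 2:
            return self.S
        ny = self.S.shape[1]
        if half_width_um is None:
            n_slab = max(1, ny // 10)
        else:
            n_slab = max(1, int(round(2 * half_width_um / self.model.dy)))
        lo = max(0, ny // 2 - n_slab // 2)
        hi = min(ny, lo + n_slab)
        return self.S[:, lo:hi, :].mean(axis=1)


@njit(cache=True, inline="always")
def _rng_next(state):
    # xorshift64* — deterministic, fast, good enough for photon transport
    s = state[0]
    s ^= s >> np.uint64(12)
    s ^= s << np.uint64(25)
    s &= np.uint64(0xFFFFFFFFFFFFFFFF)
    s ^= s >> np.uint64(27)
    state[0] = s
    return np.float64((s * np.uint64(2685821657736338717)) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _sample_hg(g, u):
    if abs(g) < 1e-6:
        return 2.0 * u - 1.0
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    cost = (1.0 + g * g - frac * frac) / (2.0 * g)
    if cost > 1.0:
        cost = 1.0
    elif cost < -1.0:
        cost = -1.0
    return cost


@njit(cache=True, inline="always")
def _fresnel_unpolarized(cos_i, n_rel):
    """Reflectance for internal incidence, n_rel = n_tissue/n_outside > 1."""
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = n_rel * n_rel * sin_i2
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = np.sqrt(1.0 - sin_t2)
    # amplitude coefficients with n1 = n_rel (inside), n2 = 1
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _mc_kernel(
    mu_a,
    mu_s,
    g_arr,
    dx,
    dy,
    dz,
    beam_radius,
    disk_beam,
    n_photons,
    seed,
    n_rel,
    use_fresnel,
    A,
):
    """Transport kernel.  Arrays are (nz, ny, nx); lengths in mm.

    With ny == 1 the medium is y-invariant: the y coordinate is unbounded
    and never indexes the grid (strip beam); otherwise the domain is a
    bounded 3-D box centred at x = y = 0 (disk beam).
    """
    nz, ny, nx = mu_a.shape
    x_half = 0.5 * nx * dx
    y_half = 0.5 * ny * dy
    depth = nz * dz
    invariant_y = ny == 1

    state = np.empty(1, dtype=np.uint64)
    state[0] = np.uint64(seed * 2654435761 + 0x9E3779B97F4A7C15)
    if state[0] == 0:
        state[0] = np.uint64(0xDEADBEEF)
    # warm up
    for _ in range(8):
        _rng_next(state)

    r_specular = 0.0
    if use_fresnel:
        r_specular = ((n_rel - 1.0) / (n_rel + 1.0)) ** 2

    tally_spec = 0.0
    tally_refl = 0.0
    tally_trans = 0.0
    tally_lat = 0.0
    tally_abs = 0.0
    roulette_net = 0.0

    for _ in range(n_photons):
        # --- launch ---
        if disk_beam:
            r = beam_radius * np.sqrt(_rng_next(state))
            phi = 6.283185307179586 * _rng_next(state)
            x = r * np.cos(phi)
            y = r * np.sin(phi)
        else:
            x = beam_radius * (2.0 * _rng_next(state) - 1.0)
            y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        if use_fresnel:
            tally_spec += r_specular
            w -= r_specular

        ix = int((x + x_half) / dx)
        if ix < 0:
            ix = 0
        elif ix >= nx:
            ix = nx - 1
        if invariant_y:
            iy = 0
        else:
            iy = int((y + y_half) / dy)
            if iy < 0:
                iy = 0
            elif iy >= ny:
                iy = ny - 1
        iz = 0

        tau = -np.log(_rng_next(state) + 1e-300)
        alive = True
        while alive:
            mua = mu_a[iz, iy, ix]
            mus = mu_s[iz, iy, ix]
            mut = mua + mus

            # distance to the nearest voxel face along the flight direction
            d_bound = 1e30
            axis = -1  # 0:x, 1:y, 2:z
            step_dir = 0
            if ux > 1e-12:
                t = ((ix + 1) * dx - x_half - x) / ux
                if t < d_bound:
                    d_bound = t
                    axis = 0
                    step_dir = 1
            elif ux < -1e-12:
                t = (ix * dx - x_half - x) / ux
                if t < d_bound:
                    d_bound = t
                    axis = 0
                    step_dir = -1
            if not invariant_y:
                if uy > 1e-12:
                    t = ((iy + 1) * dy - y_half - y) / uy
                    if t < d_bound:
                        d_bound = t
                        axis = 1
                        step_dir = 1
                elif uy < -1e-12:
                    t = (iy * dy - y_half - y) / uy
                    if t < d_bound:
                        d_bound = t
                        axis = 1
                        step_dir = -1
            if uz > 1e-12:
                t = ((iz + 1) * dz - z) / uz
                if t < d_bound:
                    d_bound = t
                    axis = 2
                    step_dir = 1
            elif uz < -1e-12:
                t = (iz * dz - z) / uz
                if t < d_bound:
                    d_bound = t
                    axis = 2
                    step_dir = -1
            if d_bound < 0.0:
                d_bound = 0.0

            if mut > 0.0 and mut * d_bound >= tau:
                # interaction inside this voxel
                d = tau / mut
                x += ux * d
                y += uy * d
                z += uz * d
                dep = w * mua / mut
                A[iz, iy, ix] += dep
                tally_abs += dep
                w -= dep
                if w <= 0.0:
                    alive = False
                    break
                # Henyey–Greenstein deflection
                gv = g_arr[iz, iy, ix]
                cost = _sample_hg(gv, _rng_next(state))
                sint = np.sqrt(max(0.0, 1.0 - cost * cost))
                phi = 6.283185307179586 * _rng_next(state)
                cosp = np.cos(phi)
                sinp = np.sin(phi)
                if abs(uz) > 0.99999:
                    ux = sint * cosp
                    uy = sint * sinp
                    uz = cost * (1.0 if uz >= 0.0 else -1.0)
                else:
                    denom = np.sqrt(1.0 - uz * uz)
                    ux_new = sint * (ux * uz * cosp - uy * sinp) / denom + ux * cost
                    uy_new = sint * (uy * uz * cosp + ux * sinp) / denom + uy * cost
                    uz_new = -sint * cosp * denom + uz * cost
                    ux = ux_new
                    uy = uy_new
                    uz = uz_new
                norm = np.sqrt(ux * ux + uy * uy + uz * uz)
                ux /= norm
                uy /= norm
                uz /= norm
                tau = -np.log(_rng_next(state) + 1e-300)
                # Russian roulette
                if w < ROULETTE_WEIGHT:
                    if _rng_next(state) < ROULETTE_SURVIVE:
                        roulette_net -= w * (1.0 / ROULETTE_SURVIVE - 1.0)
                        w /= ROULETTE_SURVIVE
                    else:
                        roulette_net += w
                        alive = False
            else:
                # traverse to the voxel face
                x += ux * d_bound
                y += uy * d_bound
                z += uz * d_bound
                tau -= mut * d_bound
                if tau < 0.0:
                    tau = 0.0
                if axis == 0:
                    ix += step_dir
                    if ix < 0 or ix >= nx:
                        tally_lat += w
                        alive = False
                elif axis == 1:
                    iy += step_dir
                    if iy < 0 or iy >= ny:
                        tally_lat += w
                        alive = False
                elif axis == 2:
                    iz += step_dir
                    if iz >= nz:
                        tally_trans += w
                        alive = False
                    elif iz < 0:
                        # upward exit through the skin surface
                        if use_fresnel:
                            cos_i = -uz
                            refl = _fresnel_unpolarized(cos_i, n_rel)
                            if _rng_next(state) < refl:
                                uz = -uz
                                iz = 0
                                z = 0.0
                            else:
                                tally_refl += w
                                alive = False
                        else:
                            tally_refl += w
                            alive = False
                else:
                    # direction parallel to all faces cannot happen for a
                    # normalized vector; guard against an infinite loop
                    alive = False

    return tally_spec, tally_refl, tally_trans, tally_lat, tally_abs, roulette_net


def run_mc(
    model: TissueModel,
    beam: Beam,
    n_photons: int = 100_000,
    seed: int = 0,
    fresnel: bool = True,
    n_tissue: float = DEFAULT_TISSUE_INDEX,
) -> tuple[SourceGrid, RunStats]:
    """Run the Monte Carlo transport and return deposition plus run statistics.

    ``S`` in the returned :class:`SourceGrid` is the fraction of incident
    energy deposited per voxel (per launched photon).
    """
    if n_photons <= 0:
        raise ValueError("n_photons must be positive")
    mu_a, mu_s, g = model.optical_grids()
    if model.is_2d:
        mu_a = mu_a[:, np.newaxis, :]
        mu_s = mu_s[:, np.newaxis, :]
        g = g[:, np.newaxis, :]
    A = np.zeros_like(mu_a)

    dx_mm = model.dx * 1e-3
    dz_mm = model.dz * 1e-3
    dy_mm = (model.dy or model.dx) * 1e-3
    radius_mm = beam.diameter_mm / 2.0
    if 2 * radius_mm > model.width_x * 1e-3:
        raise ValueError(
            f"beam diameter {beam.diameter_mm} mm exceeds the {model.width_x * 1e-3:.1f}-mm "
            "domain width; widen the geometry"
        )
    disk = not model.is_2d

    tallies = _mc_kernel(
        mu_a,
        mu_s,
        g,
        dx_mm,
        dy_mm,
        dz_mm,
        radius_mm,
        disk,
        int(n_photons),
        int(seed),
        float(n_tissue),
        bool(fresnel),
        A,
    )
    spec, refl, trans, lat, absorbed, roulette = (t / n_photons for t in tallies)
    A /= n_photons
    if model.is_2d:
        A = A[:, 0, :]
    stats = RunStats(
        n_photons=int(n_photons),
        seed=int(seed),
        specular_reflected=spec,
        diffuse_reflected=refl,
        transmitted=trans,
        escaped_lateral=lat,
        absorbed=absorbed,
        roulette_net=roulette,
    )
    return SourceGrid(S=A, model=model, beam=beam, stats=stats), stats


def source_to_power_density(
    source: SourceGrid,
    radiant_exposure: float | None = None,
    pulse_duration: float | None = None,
) -> np.ndarray:
    """Convert a deposition grid to the volumetric heat source S (W m^-3).

    ``radiant_exposure`` in J/cm^2 (defaults to the beam's); the returned
    field, integrated over the voxel volumes and the pulse duration,
    recovers the absorbed fraction of the incident energy.

    For y-invariant runs the incident energy per unit y-length of the
    strip beam is D x (beam width); deposition voxels are (dx, dz) per
    unit y-length.  For 3-D runs the incident energy is D x (disk area).
    """
    beam = source.beam
    model = source.model
    d_j_m2 = (radiant_exposure if radiant_exposure is not None else beam.radiant_exposure) * 1e4
    tau = pulse_duration if pulse_duration is not None else beam.pulse_duration
    dx_m = model.dx * 1e-6
    dz_m = model.dz * 1e-6
    if source.S.ndim == 2:
        width_m = beam.diameter_mm * 1e-3
        energy_per_voxel = source.S * d_j_m2 * width_m  # J per unit y-length
        volume = dx_m * dz_m  # m^2 per unit y-length
    else:
        radius_m = beam.diameter_mm * 1e-3 / 2.0
        energy_per_voxel = source.S * d_j_m2 * np.pi * radius_m**2
        dy_m = model.dy * 1e-6
        volume = dx_m * dy_m * dz_m
    return energy_per_voxel / (volume * tau)
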