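"""Monte Carlo transport: closed-form limits, conservation, and an
independent analog-MC oracle.

The production kernel uses weighted photons (implicit capture).  The
oracle in this file is an unweighted (analog) simulation written with
plain numpy: at every interaction the photon is absorbed outright with
probability mu_a/mu_t.  The two estimators agree in expectation, so
layer-wise absorbed fractions must match within combined Monte Carlo
error.
"""

from __future__ import annotations

import numpy as np
import pytest

from pwstherm.geometry import TissueModel
from pwstherm.mc import Beam, run_mc, source_to_power_density
from pwstherm.optics import OpticalProperties

from conftest import uniform_model


def beam_for(model, diameter_mm, dosage=1.0, wavelength=585.0):
    return Beam(
        wavelength=wavelength, diameter_mm=diameter_mm, radiant_exposure=dosage
    )


# ------------------------------------------------------- closed-form limits
def test_beer_lambert_scattering_free():
    # absorption-only medium: depth profile of deposited energy is exponential
    mu_a = 1.0  # mm^-1
    model = uniform_model(mu_a, 0.0, 0.0, nz=150, nx=40, dx=50.0, dz=20.0)
    n = 200_000
    source, stats = run_mc(model, beam_for(model, 1.0), n_photons=n, seed=3, fresnel=False)
    per_row = source.S.sum(axis=1)
    edges = np.arange(model.nz + 1) * model.dz * 1e-3  # mm
    analytic = np.exp(-mu_a * edges[:-1]) - np.exp(-mu_a * edges[1:])
    sigma = np.sqrt(np.maximum(analytic * (1 - analytic), 1e-12) / n)
    zscores = (per_row - analytic) / sigma
    # fixed seed: the whole profile sits within tight z-score bounds
    assert np.abs(zscores).max() < 4.0
    assert np.abs(zscores.mean()) < 0.5
    # total absorbed within 3 sigma of the analytic capture fraction
    p = 1.0 - np.exp(-mu_a * edges[-1])
    assert abs(stats.absorbed - p) < 3.0 * np.sqrt(p * (1 - p) / n)


def test_zero_absorption_deposits_nothing():
    model = uniform_model(0.0, 10.0, 0.8, nz=40, nx=40)
    source, stats = run_mc(model, beam_for(model, 1.0), n_photons=20_000, seed=0, fresnel=False)
    assert source.S.sum() == 0.0
    assert stats.absorbed == 0.0
    escaped = stats.diffuse_reflected + stats.transmitted + stats.escaped_lateral
    assert escaped == pytest.approx(1.0, abs=1e-12)


def test_energy_conservation():
    model = uniform_model(0.5, 15.0, 0.8, nz=60, nx=60)
    source, stats = run_mc(model, beam_for(model, 1.5), n_photons=20_000, seed=1)
    # exact bookkeeping identity including the roulette net term
    assert stats.total == pytest.approx(1.0, abs=1e-9)
    # deposition grid integrates to the absorbed tally
    assert source.S.sum() == pytest.approx(stats.absorbed, abs=1e-9)
    # the spec-level bound is far looser
    assert abs(stats.total - 1.0) < 1e-3


def test_fresnel_specular_reflection():
    model = uniform_model(1.0, 10.0, 0.8, nz=40, nx=40)
    _, stats = run_mc(model, beam_for(model, 1.0), n_photons=5_000, seed=0, fresnel=True)
    # normal-incidence specular loss for n = 1.37: ((n-1)/(n+1))^2 = 2.44%
    assert stats.specular_reflected == pytest.approx(((1.37 - 1) / (1.37 + 1)) ** 2, rel=1e-9)
    _, stats_off = run_mc(model, beam_for(model, 1.0), n_photons=5_000, seed=0, fresnel=False)
    assert stats_off.specular_reflected == 0.0


def test_seeded_reproducibility():
    model = uniform_model(0.5, 10.0, 0.8, nz=30, nx=30)
    s1, _ = run_mc(model, beam_for(model, 0.8), n_photons=5_000, seed=11)
    s2, _ = run_mc(model, beam_for(model, 0.8), n_photons=5_000, seed=11)
    np.testing.assert_array_equal(s1.S, s2.S)
    s3, _ = run_mc(model, beam_for(model, 0.8), n_photons=5_000, seed=12)
    assert not np.array_equal(s1.S, s3.S)


def test_beam_wider_than_domain_rejected():
    model = uniform_model(0.5, 10.0, 0.8, nz=20, nx=10, dx=50.0)  # 0.5 mm wide
    with pytest.raises(ValueError, match="beam"):
        run_mc(model, beam_for(model, 6.0), n_photons=100)


def test_melanin_increases_epidermal_absorption():
    from pwstherm.synthetic import make_single_vessel_case

    kwargs = dict(
        diameter_um=0.0, wavelength=585.0, width_x_um=3000.0, depth_z_um=2000.0,
        dx_um=20.0, dz_um=10.0,
    )
    light = make_single_vessel_case(pigmentation="light", **kwargs)
    heavy = make_single_vessel_case(pigmentation="heavy", **kwargs)
    beam = Beam(wavelength=585.0, diameter_mm=1.0, radiant_exposure=1.0)
    s_light, st_light = run_mc(light, beam, n_photons=20_000, seed=5)
    s_heavy, st_heavy = run_mc(heavy, beam, n_photons=20_000, seed=5)
    basal = light.labels == 2
    assert s_heavy.S[basal].sum() > 5.0 * s_light.S[basal].sum()
    assert st_heavy.absorbed > st_light.absorbed


# ------------------------------------------------------- analog oracle
def _analog_two_layer(n, mu_a, mu_s, g, z_boundary, z_max, seed):
    """Unweighted analog MC in a laterally infinite two-layer slab.

    Returns (absorbed_layer1, absorbed_layer2, reflected, transmitted)
    as photon-count fractions.  Layer 1 occupies z in [0, z_boundary),
    layer 2 [z_boundary, z_max); no refractive-index mismatch.
    """
    rng = np.random.default_rng(seed)
    pos = np.zeros((n, 3))
    direction = np.tile([0.0, 0.0, 1.0], (n, 1))
    alive = np.ones(n, dtype=bool)
    absorbed_layer = np.zeros(n, dtype=np.int8)  # 0 = escaped
    reflected = np.zeros(n, dtype=bool)
    transmitted = np.zeros(n, dtype=bool)

    while alive.any():
        idx = np.flatnonzero(alive)
        layer = (pos[idx, 2] >= z_boundary).astype(int)
        mt = mu_a[layer] + mu_s[layer]
        step = -np.log(rng.random(idx.size)) / mt
        # propagate, allowing a single boundary crossing per step by
        # re-sampling the remaining optical depth in the new layer
        new_z = pos[idx, 2] + direction[idx, 2] * step
        crossing = ((pos[idx, 2] < z_boundary) & (new_z >= z_boundary)) | (
            (pos[idx, 2] >= z_boundary) & (new_z < z_boundary)
        )
        if crossing.any():
            c = idx[crossing]
            dz_to_b = (z_boundary - pos[c, 2]) / direction[c, 2]
            used = dz_to_b * mt[crossing]
            total_depth = step[crossing] * mt[crossing]
            other = (pos[c, 2] < z_boundary).astype(int)  # the layer entered
            mt_other = mu_a[other] + mu_s[other]
            extra = (total_depth - used) / mt_other
            step[crossing] = dz_to_b + extra
        pos[idx] += direction[idx] * step[:, None]

        z = pos[idx, 2]
        out_top = z < 0
        out_bottom = z >= z_max
        reflected[idx[out_top]] = True
        transmitted[idx[out_bottom]] = True
        alive[idx[out_top | out_bottom]] = False

        inside = idx[~(out_top | out_bottom)]
        if inside.size == 0:
            continue
        layer = (pos[inside, 2] >= z_boundary).astype(int)
        absorb = rng.random(inside.size) < mu_a[layer] / (mu_a[layer] + mu_s[layer])
        hit = inside[absorb]
        absorbed_layer[hit] = layer[absorb] + 1
        alive[hit] = False

        scat = inside[~absorb]
        if scat.size:
            g_s = g[layer[~absorb]]
            u = rng.random(scat.size)
            cos_t = np.where(
                g_s == 0.0,
                2 * u - 1,
                (1 + g_s**2 - ((1 - g_s**2) / (1 - g_s + 2 * g_s * u)) ** 2)
                / (2 * g_s),
            )
            sin_t = np.sqrt(np.maximum(0.0, 1 - cos_t**2))
            phi = 2 * np.pi * rng.random(scat.size)
            ux, uy, uz = direction[scat].T
            near_vertical = np.abs(uz) > 0.99999
            denom = np.sqrt(np.maximum(1e-30, 1 - uz**2))
            nx = sin_t * (ux * uz * np.cos(phi) - uy * np.sin(phi)) / denom + ux * cos_t
            ny = sin_t * (uy * uz * np.cos(phi) + ux * np.sin(phi)) / denom + uy * cos_t
            nz = -sin_t * np.cos(phi) * denom + uz * cos_t
            nx = np.where(near_vertical, sin_t * np.cos(phi), nx)
            ny = np.where(near_vertical, sin_t * np.sin(phi), ny)
            nz = np.where(near_vertical, np.sign(uz) * cos_t, nz)
            norm = np.sqrt(nx**2 + ny**2 + nz**2)
            direction[scat] = np.stack([nx / norm, ny / norm, nz / norm], axis=1)

    return (
        float((absorbed_layer == 1).mean()),
        float((absorbed_layer == 2).mean()),
        float(reflected.mean()),
        float(transmitted.mean()),
    )


def test_weighted_mc_matches_analog_oracle():
    # two-layer slab, laterally wide enough that side losses are negligible
    mu_a = np.array([0.5, 0.2])
    mu_s = np.array([5.0, 8.0])
    g = np.array([0.7, 0.9])
    z_boundary_mm, z_max_mm = 1.0, 4.0

    labels = np.full((200, 400), 3, dtype=np.int8)
    labels[:50, :] = 1  # first 1 mm (dz = 20 um)
    model = TissueModel(
        labels=labels,
        dx=100.0,
        dz=20.0,
        optical_by_label={
            1: OpticalProperties(mu_a[0], mu_s[0], g[0]),
            3: OpticalProperties(mu_a[1], mu_s[1], g[1]),
        },
    )
    n = 20_000
    source, stats = run_mc(
        model, beam_for(model, 0.5), n_photons=n, seed=21, fresnel=False
    )
    a1 = source.S[:50, :].sum()
    a2 = source.S[50:, :].sum()

    n_o = 20_000
    o1, o2, orefl, otrans = _analog_two_layer(
        n_o, mu_a, mu_s, g, z_boundary_mm, z_max_mm, seed=22
    )

    for ours, oracle in ((a1, o1), (a2, o2), (stats.diffuse_reflected, orefl)):
        p = max(min(oracle, 1 - oracle), 1e-6)
        sigma = np.sqrt(p * (1 / n + 1 / n_o))
        assert abs(ours - oracle) < 4.0 * sigma, (ours, oracle, sigma)


# ------------------------------------------------------- source conversion
def test_source_power_density_energy_bookkeeping_2d():
    model = uniform_model(1.0, 10.0, 0.8, nz=50, nx=40, dx=50.0, dz=20.0)
    beam = Beam(wavelength=585.0, diameter_mm=1.0, radiant_exposure=5.0)
    source, stats = run_mc(model, beam, n_photons=10_000, seed=2, fresnel=False)
    power = source_to_power_density(source)
    # energy per unit y-length: strip beam of width D_beam at 5 J/cm^2
    incident_per_m = 5.0 * 1e4 * beam.diameter_mm * 1e-3
    voxel_area_m2 = model.dx * 1e-6 * model.dz * 1e-6
    deposited_per_m = power.sum() * voxel_area_m2 * beam.pulse_duration
    assert deposited_per_m == pytest.approx(stats.absorbed * incident_per_m, rel=1e-9)


def test_source_power_density_energy_bookkeeping_3d():
    model = uniform_model(
        1.0, 10.0, 0.8, nz=30, nx=30, ny=30, dx=50.0, dz=20.0, dy=50.0
    )
    beam = Beam(wavelength=585.0, diameter_mm=1.0, radiant_exposure=2.0)
    source, stats = run_mc(model, beam, n_photons=10_000, seed=2, fresnel=False)
    power = source_to_power_density(source)
    incident = 2.0 * 1e4 * np.pi * (beam.diameter_mm * 1e-3 / 2) ** 2
    voxel_m3 = model.dx * model.dy * model.dz * 1e-18
    deposited = power.sum() * voxel_m3 * beam.pulse_duration
    assert deposited == pytest.approx(stats.absorbed * incident, rel=1e-9)


def test_central_slab_averaging():
    model = uniform_model(
        1.0, 5.0, 0.8, nz=10, nx=10, ny=11, dx=50.0, dz=20.0, dy=50.0
    )
    source, _ = run_mc(model, beam_for(model, 0.3), n_photons=2_000, seed=4, fresnel=False)
    slab = source.central_slab(75.0)  # 3 central y planes (dy = 50 um)
    manual = source.S[:, 4:7, :].mean(axis=1)
    np.testing.assert_allclose(slab, manual)
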