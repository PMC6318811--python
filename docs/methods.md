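# Methods

This package simulates photothermal treatment of port-wine-stain (PWS)
vasculature: pulsed laser irradiation of layered human skin whose vessels
may carry indocyanine-green-doped erythrocyte-derived particles (NETs),
with cryogen-spray pre-cooling of the surface. The pipeline is

1. **geometry** — voxelized tissue model (epidermis / basal layer /
   dermis / vessels) with per-label optical and thermal properties;
2. **photon transport** — Monte Carlo simulation of the laser pulse,
   producing the volumetric heat source;
3. **heat diffusion** — 2-D finite-difference solution of the heat
   equation over the cooling → pulse → rewarming timeline;
4. **thermal damage** — Arrhenius damage integral and derived metrics
   (% vessel damage, epidermal damage flag, threshold dosage).

## Optical model

All coefficients are in mm⁻¹; wavelengths in nm (valid range 400–1100).

- Baseline (bloodless, melaninless) skin absorption:
  `mu_a_base = 0.0244 + 8.53·exp(−(λ−154)/66.2)`.
- Melanosome absorption `mu_a_mel = 6.6e10·λ^−3.33`; the 15-µm basal
  layer is a volume mixture `fmel·mu_a_mel + (1−fmel)·mu_a_base` with
  `fmel` = 0.04 / 0.15 / 0.50 for light / moderate / heavy pigmentation.
- Skin scattering `mu_s = (2e4·λ^−1.5 + 2e11·λ^−4)/(1−g)` with g = 0.80
  at 585 nm and 0.91 at 755 nm.
- Blood (45% hematocrit, 70% SO₂) is tabulated at the two treatment
  wavelengths only: (17.91, 76.05, 0.970) at 585 nm and
  (0.44, 79.85, 0.983) at 755 nm for (µa, µs, g).
- **Unresolved-plexus dermis** (simulated geometries): six depth bins,
  each with a representative vessel radius `r_i` and blood fraction
  `f_i`; the dermal absorption is
  `f_i·C_i·mu_a_blood + (1−f_i)·mu_a_base`, where the screening factor
  `C_i = 0.039 + 0.486·exp(−mu_a_blood·r_i/0.193) + 0.468·exp(−mu_a_blood·r_i/0.914)`
  accounts for shielding of vessel cores. The screening exponent uses
  the mixed unit convention µa in mm⁻¹ × r in µm, which is the only
  convention that reproduces the published per-bin values.
- **Explicit-vessel dermis** (imported 3-D masks): plain mixture with
  0.2% blood volume fraction, no screening correction.
- **NET-laden vessels**: each of µa, µs, g mixes linearly by volume
  fraction between blood and the particle suspension. Micro NETs have
  (µs, g) = (2.20 mm⁻¹, 0.99); nano NETs (0.06 mm⁻¹, 0.55), both at
  755 nm. The ICG fabrication-buffer concentration needed for a target
  vessel absorption is `[ICG] (µM) = 17.8·(mu_a_BV − (1−f)·mu_a_blood)/f`.

## Geometry

z increases downward from the surface; voxels are half-open intervals,
x = 0 at the beam centre. The epidermis is 45 µm of melaninless tissue
over a 15-µm basal layer (snapped to whole voxels; defaults dz = 5 µm,
dx = 10 µm). Simulated PWS geometries are y-invariant 2-D cross-sections
with y-parallel cylindrical vessels; imported masks give full 3-D models
with an epidermis prepended above the mask volume.

**Domain padding.** Photon transport defaults to a 12 mm × 4 mm domain
even though the thermal/damage box of interest is |x| ≤ 1 mm × 2 mm.
Real dermis and subcutis continue beyond the box and back-scatter
photons into it; with a 2-mm-deep transport box, ~35% of 755-nm energy
exits the bottom face and the vessel temperature rise is underestimated
by ~15%. A convergence study of the peak adiabatic vessel temperature
rise (depth 2/4/6/8 mm → 67.1/78.5/79.1/78.3 °C; width 8/12/16 mm →
78.5/80.1/79.8 °C) fixed the 12 × 4 mm default; heat and damage are then
solved on the cropped tissue box.

## Monte Carlo photon transport

Weighted photons with implicit capture: at each interaction a photon
deposits `w·mu_a/mu_t` in the local voxel; direction updates sample the
Henyey–Greenstein phase function; Russian roulette (threshold 1e-4,
survival 0.1) terminates low-weight photons without bias. The surface
applies Fresnel specular loss at entry and unpolarized
reflection/total-internal-reflection at exit (n_tissue = 1.37 vs air).
The kernel is a numba-compiled voxel traversal (per-axis face
distances); the RNG is xorshift64*, seeded from the run seed, so runs
are bit-reproducible.

For y-invariant models the flat-top circular beam is replaced by a
strip beam (launch x ~ U(−R, R), score in (x, z)): for an infinite
cylinder the deposition per unit y-length depends only on the lateral
launch profile, and the incident energy per unit y is D × beam width.
Full 3-D models launch a uniform disk and score in (x, y, z); the
volumetric power density for the 2-D thermal solver is averaged over a
central y-slab.

Energy bookkeeping is exact: specular + diffuse reflection +
transmission + lateral escape + absorption + roulette net ≡ 1 to
machine precision, and the deposition grid integrates to the absorbed
fraction.

## Heat diffusion

2-D control-volume finite differences on the x–z grid, backward Euler
in time, harmonic-mean face conductivities, adiabatic far-field sides
and bottom. The convective surface condition
`−κ∂T/∂z = h(Tmed − T)` is folded into the top row through the series
resistance `U = 1/(1/h + dz/(2κ))`, which accounts for the half-cell
conduction path to the node centre. One sparse LU factorization is
cached per (time step, cooling phase).

Thermal properties: ρ = 1200 kg m⁻³, C = 3600 J kg⁻¹ °C⁻¹ everywhere;
κ = 0.26 W m⁻¹ °C⁻¹ in the epidermis/basal layer and 0.53 in dermis and
vessels. Baseline temperature 35 °C.

The default timeline models cryogen-spray cooling: spurt
(h = 4000 W m⁻² °C⁻¹, −50 °C, 100 ms), residual pool (3000, −26 °C,
200 ms), rewarming (10, 25 °C, 500 ms); a 3-ms laser pulse fires at
100–103 ms. Default steps: 0.05 ms during the pulse, 0.5 ms before,
1 ms after; the schedule places exact breakpoints at phase and pulse
edges.

Verification: the solver matches the semi-infinite convective-cooling
erfc solution to <1% of the span, satisfies a discrete energy balance
to machine precision, and a uniform adiabatic pulse reproduces
ΔT = S·τ/(ρC) exactly.

## Thermal damage

Arrhenius integral `Ω = A∫exp(−Eₐ/(R·T_K))dt` from pulse onset to the
end of rewarming, trapezoidal in time, streamed through a callback so
the full temperature history never needs to be stored. Kinetics:
skin (A = 1.8e51 s⁻¹, Eₐ = 327 kJ/mol), blood/vessels (7.6e66, 455
kJ/mol). Ω ≥ 1 marks irreversible damage. `% vessel damage` is the
percentage of vessel cross-section nodes with Ω ≥ 1 (optionally limited
to 1 mm depth for plexus geometries); the epidermal flag is any
epidermal node with Ω ≥ 1.

**Threshold dosage search.** The heat equation is linear in the source,
so `T_D(t) = T₀(t) + D·(T₁(t) − T₀(t))` with T₀ the cooling-only and T₁
the unit-dosage solution. Two thermal solves therefore price every
candidate dosage; Ω is monotone in D, so a binary search on the dosage
grid returns the largest non-damaging dosage. For vessel-free skin the
problem has no lateral structure and is solved on a thin lateral strip
with the laterally averaged deposition profile, making a full
wavelength × pigmentation threshold table a few-second computation.

## OCT preprocessing and synthetic plexus volumes

The preprocessing chain mirrors the published sequence: per-en-face FFT
with a separable hard band mask (horizontal pass band [0.1, 1.0] ×
Nyquist, vertical [0, 0.01]), global/Otsu thresholding, 3³ median
despeckling.

**Operating envelope of the band filter**: the horizontal high-pass
removes spatial periods longer than 20 pixels, so it erases the
interior of features wider than ~20 px while fully removing scan-line
drift (structures uniform along x). At 10-µm pitch a 200-µm vessel is
exactly 20 px wide; segmentation of such plexuses should therefore rely
on Otsu + median (Jaccard ≈ 0.95–0.98 against ground truth at generator
defaults), with the FFT step reserved for drift-dominated data with
narrow vessels.

The synthetic generator replaces the unavailable patient OCT volume: it
draws near-y-oriented tubes (log-normal diameters, mode 200 µm, clipped
to 60–650 µm; centre depths ≤ 1 mm; a 20% fraction tilted ≤ 5°),
convolves with a small Gaussian PSF, applies gamma multiplicative
speckle (default shape 10, i.e. ≈32% relative std as after ~10-frame
averaging) and adds a smooth scan-line drift uniform along x. It
returns the noisy volume, the clean ground-truth mask, and the drawn
parameters, and is bit-reproducible under a seed.

## Numerical defaults and limitations

- Fast mode uses 1e5 photons (full mode 1e6); % damage metrics then
  carry ~±1.5 pp Monte Carlo noise (~±0.5 pp at 1e6). Point metrics
  compared against reference values use the full 1e6-photon budget so
  the comparison measures the model rather than the seed.
- The thermal solver is 2-D (y-invariant); 3-D geometries are reduced
  by central-slab averaging before the thermal step, which neglects
  y-diffusion out of the slab.
- Blood properties are tabulated at 585 and 755 nm only; other
  wavelengths raise rather than interpolate.
- Vessels are straight cylinders or imported voxel masks; no curved or
  branching primitives, no surface topography.
- The micro/nano formulation contrast is physically small at 10% NET
  volume fraction (vessel g changes by ~0.04); formulation-ordering
  comparisons are made at 25% volume fraction where the scattering
  contrast is large relative to Monte Carlo noise.
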