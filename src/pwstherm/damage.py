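"""Arrhenius thermal-damage quantification and threshold-dosage search.

Damage is the first-order rate-process integral

    Omega(x, z) = A * integral_0^tau exp(-E / (R T(x, z, t))) dt

with T in kelvin; Omega = 1 marks irreversible damage to 63% of the
tissue.  Bulk skin and blood use different (A, E) pairs.  The integral is
accumulated from laser onset through the end of the rewarming interval
(the pre-pulse cooled skin contributes nothing measurable) by the
trapezoid rule applied to the integrand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from pwstherm.geometry import (
    LABEL_BASAL,
    LABEL_DERMIS,
    LABEL_EPIDERMIS,
    LABEL_VESSEL,
    TissueModel,
)
from pwstherm.heat import (
    DEFAULT_COOLING_PHASES,
    CoolingPhase,
    TemperatureField,
    iterate_temperature,
)

__all__ = [
    "GAS_CONSTANT",
    "ArrheniusParams",
    "SKIN_ARRHENIUS",
    "BLOOD_ARRHENIUS",
    "DEFAULT_ARRHENIUS_BY_LABEL",
    "DamageField",
    "arrhenius_integrand",
    "ArrheniusAccumulator",
    "damage_integral",
    "percent_vessel_damage",
    "epidermis_damaged",
    "find_threshold_dosage",
]

GAS_CONSTANT = 8.314  # J mol^-1 K^-1
CELSIUS_TO_KELVIN = 273.15


@dataclass(frozen=True)
class ArrheniusParams:
    """Frequency factor A (s^-1) and activation energy E (J mol^-1)."""

    a: float
    e: float

    def omega_at_constant_temperature(self, t_celsius: float, duration: float) -> float:
        """Closed form A * tau * exp(-E/(R T)) for a constant temperature."""
        t_k = t_celsius + CELSIUS_TO_KELVIN
        return self.a * duration * np.exp(-self.e / (GAS_CONSTANT * t_k))


SKIN_ARRHENIUS = ArrheniusParams(1.8e51, 327_000.0)
BLOOD_ARRHENIUS = ArrheniusParams(7.6e66, 455_000.0)

DEFAULT_ARRHENIUS_BY_LABEL = {
    LABEL_EPIDERMIS: SKIN_ARRHENIUS,
    LABEL_BASAL: SKIN_ARRHENIUS,
    LABEL_DERMIS: SKIN_ARRHENIUS,
    LABEL_VESSEL: BLOOD_ARRHENIUS,
}


@dataclass
class DamageField:
    """Damage index Omega per node and the Omega >= 1 mask."""

    omega: np.ndarray
    model: TissueModel = field(repr=False)

    @property
    def mask(self) -> np.ndarray:
        return self.omega >= 1.0


def _param_grids(
    model: TissueModel, params_by_label: dict[int, ArrheniusParams] | None
) -> tuple[np.ndarray, np.ndarray]:
    params_by_label = params_by_label or DEFAULT_ARRHENIUS_BY_LABEL
    a = np.zeros(model.labels.shape)
    e = np.full(model.labels.shape, np.inf)
    for label, p in params_by_label.items():
        sel = model.labels == label
        a[sel] = p.a
        e[sel] = p.e
    return a, e


def arrhenius_integrand(t_celsius: np.ndarray, a: np.ndarray, e: np.ndarray) -> np.ndarray:
    """A exp(-E/(R T_K)) for temperature in deg C (elementwise)."""
    t_k = np.asarray(t_celsius, dtype=float) + CELSIUS_TO_KELVIN
    return a * np.exp(-e / (GAS_CONSTANT * t_k))


class ArrheniusAccumulator:
    """Streaming trapezoid integration of the Arrhenius integrand.

    Feed it (t, dt, T) steps (e.g. as a ``solve_heat`` callback); it
    accumulates Omega between ``t_start`` and ``t_end`` without retaining
    the temperature history.
    """

    def __init__(
        self,
        model: TissueModel,
        t_start: float,
        t_end: float = np.inf,
        params_by_label: dict[int, ArrheniusParams] | None = None,
    ) -> None:
        self._a, self._e = _param_grids(model, params_by_label)
        self.t_start = t_start
        self.t_end = t_end
        self.omega = np.zeros(model.labels.shape)
        self._prev_t: float | None = None
        self._prev_f: np.ndarray | None = None
        self.model = model

    def __call__(self, t: float, dt: float, temperature: np.ndarray) -> None:
        if t < self.t_start - 1e-12 or t > self.t_end + 1e-12:
            return
        f = arrhenius_integrand(temperature, self._a, self._e)
        if self._prev_f is not None:
            self.omega += 0.5 * (t - self._prev_t) * (f + self._prev_f)
        self._prev_t = t
        self._prev_f = f

    def result(self) -> DamageField:
        return DamageField(omega=self.omega, model=self.model)


def damage_integral(
    temperature_field: TemperatureField,
    model: TissueModel | None = None,
    params_by_label: dict[int, ArrheniusParams] | None = None,
    t_start: float | None = None,
    t_end: float | None = None,
) -> DamageField:
    """Integrate the Arrhenius integrand over a stored temperature history.

    By default the integration spans laser onset through the end of the
    run (the end of the rewarming interval).
    """
    if temperature_field.history is None:
        raise ValueError(
            "temperature history was not stored; use ArrheniusAccumulator as a "
            "solve_heat callback for streaming integration"
        )
    model = model or temperature_field.model
    t_start = temperature_field.pulse_start if t_start is None else t_start
    t_end = temperature_field.times[-1] if t_end is None else t_end
    acc = ArrheniusAccumulator(model, t_start, t_end, params_by_label)
    for t, T in zip(temperature_field.times, temperature_field.history):
        acc(t, 0.0, T)
    return acc.result()


def percent_vessel_damage(
    damage: DamageField,
    model: TissueModel | None = None,
    depth_limit_um: float | None = None,
) -> float:
    """Percent of vessel cross-section nodes with Omega >= 1.

    ``depth_limit_um`` restricts the count to vessel nodes with centre
    depth <= the limit (used for plexus geometries, e.g. 1000 um).
    """
    model = model or damage.model
    vessel = model.vessel_mask()
    if depth_limit_um is not None:
        z = model.z_centers()
        depth_ok = z <= depth_limit_um
        vessel = vessel & depth_ok.reshape((-1,) + (1,) * (vessel.ndim - 1))
    n_vessel = int(vessel.sum())
    if n_vessel == 0:
        raise ValueError("no vessel nodes in the model (within the depth limit)")
    return 100.0 * float((damage.omega[vessel] >= 1.0).sum()) / n_vessel


def epidermis_damaged(damage: DamageField, model: TissueModel | None = None) -> bool:
    """True iff any epidermal (melaninless or basal) node reached Omega >= 1."""
    model = model or damage.model
    epi = model.epidermis_mask()
    if not epi.any():
        raise ValueError("model has no epidermal nodes")
    return bool((damage.omega[epi] >= 1.0).any())


def find_threshold_dosage(
    model: TissueModel,
    source_unit: np.ndarray,
    phases: Sequence[CoolingPhase] = DEFAULT_COOLING_PHASES,
    pulse_start_ms: float = 100.0,
    pulse_duration_ms: float = 3.0,
    dosage_step: float = 1.0,
    max_dosage: float = 50.0,
    params_by_label: dict[int, ArrheniusParams] | None = None,
    dt_pulse_ms: float = 0.05,
    dt_cool_ms: float = 0.5,
    dt_post_ms: float = 1.0,
) -> float:
    """Largest dosage on a grid that leaves the epidermis undamaged.

    ``source_unit`` is the volumetric power density for a unit (1 J/cm^2)
    incident dosage.  The heat equation is linear, so the temperature
    history at dosage D is T_D(t) = T_0(t) + D * (T_1(t) - T_0(t)) with
    T_0 the cooling-only and T_1 the unit-dosage solution; two thermal
    solves therefore cover every candidate dosage, and the epidermal
    damage index is evaluated per candidate on the stored epidermal
    histories.  Omega is monotone in D (the unit response is non-negative
    by the maximum principle), so the returned value is the largest
    non-damaging dosage on the grid ``dosage_step * {0, 1, 2, ...}``.

    Returns 0 with a warning when even the smallest positive candidate
    damages the epidermis.
    """
    epi = model.epidermis_mask()
    if not epi.any():
        raise ValueError("model has no epidermal nodes")

    def epidermal_history(src: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
        times, rows = [], []
        for t, dt, T in iterate_temperature(
            model,
            src,
            phases,
            pulse_start_ms,
            pulse_duration_ms,
            dt_pulse_ms,
            dt_cool_ms,
            dt_post_ms,
        ):
            times.append(t)
            rows.append(T[epi].copy())
        return np.asarray(times), np.asarray(rows)

    times, hist0 = epidermal_history(None)
    _, hist1 = epidermal_history(source_unit)
    unit_response = hist1 - hist0

    params_by_label = params_by_label or DEFAULT_ARRHENIUS_BY_LABEL
    a_grid, e_grid = _param_grids(model, params_by_label)
    a_epi = a_grid[epi]
    e_epi = e_grid[epi]

    pulse_start = pulse_start_ms * 1e-3
    in_window = times >= pulse_start - 1e-12
    t_w = times[in_window]
    h0 = hist0[in_window]
    du = unit_response[in_window]

    def damaged_at(dosage: float) -> bool:
        f = arrhenius_integrand(h0 + dosage * du, a_epi, e_epi)
        omega = np.trapezoid(f, t_w, axis=0)
        return bool((omega >= 1.0).any())

    n_grid = int(np.floor(max_dosage / dosage_step + 1e-9))
    candidates = dosage_step * np.arange(1, n_grid + 1)
    # binary search for the first damaging dosage (Omega monotone in D)
    lo, hi = 0, len(candidates)  # candidates[:lo] safe, candidates[hi:] damaging
    while lo < hi:
        mid = (lo + hi) // 2
        if damaged_at(candidates[mid]):
            hi = mid
        else:
            lo = mid + 1
    if lo == 0:
        warnings.warn(
            f"every candidate dosage >= {dosage_step} J/cm^2 damages the epidermis; "
            "returning 0"
        )
        return 0.0
    return float(candidates[lo - 1])
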