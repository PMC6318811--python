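"""Transient heat diffusion under cryogen-spray cooling.

Solves the 2-D heat equation

    rho C dT/dt = div(kappa grad T) + S(x, z)

on the tissue voxel grid with a convective (Robin) boundary at the skin
surface, -kappa dT/dz|_{z=0} = h (T_med - T_surface), and adiabatic
far-field boundaries.  The surface condition cycles through the cryogen
phases (spurt, residual pool, rewarming), each with its own convective
coefficient h and film temperature T_med; the laser source is active only
during the pulse window, which by default falls inside the pool-residence
phase immediately after the 100-ms spurt.

Discretization: node-centred control volumes with harmonic-mean face
conductivities and backward-Euler time stepping (unconditionally stable);
the surface Robin condition is folded into the top row through the series
resistance of the half-cell and the convective film.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from pwstherm.geometry import TissueModel

__all__ = [
    "CoolingPhase",
    "DEFAULT_COOLING_PHASES",
    "TemperatureField",
    "solve_heat",
    "iterate_temperature",
    "peak_temperature_map",
    "BASELINE_SKIN_TEMPERATURE",
]

BASELINE_SKIN_TEMPERATURE = 35.0  # deg C


@dataclass(frozen=True)
class CoolingPhase:
    """One surface-cooling phase: convective coefficient, film temperature, duration."""

    h: float  # W m^-2 C^-1
    t_med: float  # deg C
    duration_ms: float

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError("convective coefficient must be >= 0")
        if self.duration_ms <= 0:
            raise ValueError("phase duration must be positive")


#: cryogen spurt (100 ms), residual pool (200 ms), rewarming (500 ms)
DEFAULT_COOLING_PHASES = (
    CoolingPhase(4000.0, -50.0, 100.0),
    CoolingPhase(3000.0, -26.0, 200.0),
    CoolingPhase(10.0, 25.0, 500.0),
)


@dataclass
class TemperatureField:
    """Temperature history of a heat-solver run.

    ``history`` is ``(n_times, nz, nx)`` when full storage was requested,
    otherwise only ``snapshots`` (a decimated history) is kept.
    ``peak`` is the nodewise maximum over the whole run, including the
    initial condition.
    """

    times: np.ndarray  # s
    history: np.ndarray | None
    snapshots: np.ndarray | None
    snapshot_times: np.ndarray | None
    final: np.ndarray
    peak: np.ndarray
    pulse_start: float  # s
    pulse_end: float  # s
    model: TissueModel = field(repr=False)


def _assemble_operator(
    model: TissueModel, h: float, dt: float
) -> tuple[object, np.ndarray, float]:
    """Backward-Euler system matrix for one (phase, dt) combination.

    Returns (LU factorization, Robin source vector coefficient array
    b_robin such that rhs += b_robin * T_med, rho_c/dt scalar field).
    """
    kappa, rho, c = model.thermal_grids()
    if not model.is_2d:
        raise ValueError("the thermal solver is 2-D; pass an x–z model")
    nz, nx = kappa.shape
    dz = model.dz * 1e-6
    dx = model.dx * 1e-6
    n = nz * nx
    idx = np.arange(n).reshape(nz, nx)
    rho_c = (rho * c).ravel()

    rows, cols, vals = [], [], []
    diag = np.zeros(n)

    # vertical faces (z direction)
    k1 = kappa[:-1, :]
    k2 = kappa[1:, :]
    kf = 2.0 * k1 * k2 / (k1 + k2)
    coef = (kf / dz**2).ravel()
    a = idx[:-1, :].ravel()
    b = idx[1:, :].ravel()
    rows += [a, b]
    cols += [b, a]
    vals += [coef, coef]
    np.add.at(diag, a, -coef)
    np.add.at(diag, b, -coef)

    # horizontal faces (x direction)
    k1 = kappa[:, :-1]
    k2 = kappa[:, 1:]
    kf = 2.0 * k1 * k2 / (k1 + k2)
    coef = (kf / dx**2).ravel()
    a = idx[:, :-1].ravel()
    b = idx[:, 1:].ravel()
    rows += [a, b]
    cols += [b, a]
    vals += [coef, coef]
    np.add.at(diag, a, -coef)
    np.add.at(diag, b, -coef)

    # Robin surface condition on the top row: series resistance of the
    # convective film and the half-cell conduction path
    b_robin = np.zeros(n)
    if h > 0:
        top = idx[0, :]
        u = 1.0 / (1.0 / h + dz / (2.0 * kappa[0, :]))
        diag[top] -= u / dz
        b_robin[top] = u / dz

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    lap = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    lap += sp.diags(diag)

    system = sp.diags(rho_c / dt) - lap
    return splu(system.tocsc()), b_robin, rho_c


def _build_schedule(
    phases: Sequence[CoolingPhase],
    pulse_start: float,
    pulse_end: float,
    dt_pulse: float,
    dt_cool: float,
    dt_post: float,
) -> list[tuple[float, float, float, int]]:
    """Split the timeline into (t0, t1, dt, phase_index) intervals (seconds)."""
    breaks = {0.0, pulse_start, pulse_end}
    t = 0.0
    phase_edges = []
    for p in phases:
        t += p.duration_ms * 1e-3
        phase_edges.append(t)
        breaks.add(t)
    t_total = phase_edges[-1]
    if pulse_end > t_total:
        raise ValueError("pulse window extends beyond the cooling timeline")
    pts = sorted(b for b in breaks if 0.0 <= b <= t_total)
    intervals = []
    for t0, t1 in zip(pts[:-1], pts[1:]):
        if t1 - t0 <= 1e-12:
            continue
        mid = 0.5 * (t0 + t1)
        phase_idx = next(i for i, e in enumerate(phase_edges) if mid < e + 1e-12)
        if pulse_start <= mid < pulse_end:
            dt = dt_pulse
        elif mid < pulse_start:
            dt = dt_cool
        else:
            dt = dt_post
        intervals.append((t0, t1, dt, phase_idx))
    return intervals


def iterate_temperature(
    model: TissueModel,
    source: np.ndarray | None,
    phases: Sequence[CoolingPhase] = DEFAULT_COOLING_PHASES,
    pulse_start_ms: float = 100.0,
    pulse_duration_ms: float = 3.0,
    dt_pulse_ms: float = 0.05,
    dt_cool_ms: float = 0.5,
    dt_post_ms: float = 1.0,
    t_initial: float = BASELINE_SKIN_TEMPERATURE,
) -> Iterator[tuple[float, float, np.ndarray]]:
    """Yield (time, dt, temperature) after every implicit step.

    ``source`` is the volumetric power density (W m^-3) active during the
    pulse window only; pass None for a cooling-only run.  The initial
    state (t = 0) is yielded first with dt = 0.
    """
    nz, nx = model.labels.shape
    if source is not None and source.shape != (nz, nx):
        raise ValueError(
            f"source grid {source.shape} is not co-registered with the model {(nz, nx)}"
        )
    pulse_start = pulse_start_ms * 1e-3
    pulse_end = pulse_start + pulse_duration_ms * 1e-3
    schedule = _build_schedule(
        phases, pulse_start, pulse_end, dt_pulse_ms * 1e-3, dt_cool_ms * 1e-3, dt_post_ms * 1e-3
    )

    T = np.full(nz * nx, float(t_initial))
    yield 0.0, 0.0, T.reshape(nz, nx)

    lu_cache: dict[tuple[float, int], tuple[object, np.ndarray, np.ndarray]] = {}
    s_flat = None if source is None else source.ravel()

    for t0, t1, dt, phase_idx in schedule:
        n_steps = max(1, int(round((t1 - t0) / dt)))
        dt_eff = (t1 - t0) / n_steps
        key = (round(dt_eff, 12), phase_idx)
        if key not in lu_cache:
            lu, b_robin, rho_c = _assemble_operator(model, phases[phase_idx].h, dt_eff)
            lu_cache[key] = (lu, b_robin, rho_c)
        lu, b_robin, rho_c = lu_cache[key]
        t_med = phases[phase_idx].t_med
        in_pulse = s_flat is not None and t0 >= pulse_start - 1e-12 and t1 <= pulse_end + 1e-12
        t = t0
        for _ in range(n_steps):
            rhs = rho_c / dt_eff * T + b_robin * t_med
            if in_pulse:
                rhs = rhs + s_flat
            T = lu.solve(rhs)
            t += dt_eff
            yield t, dt_eff, T.reshape(nz, nx)


def solve_heat(
    model: TissueModel,
    source: np.ndarray | None,
    phases: Sequence[CoolingPhase] = DEFAULT_COOLING_PHASES,
    pulse_start_ms: float = 100.0,
    pulse_duration_ms: float = 3.0,
    dt_pulse_ms: float = 0.05,
    dt_cool_ms: float = 0.5,
    dt_post_ms: float = 1.0,
    t_initial: float = BASELINE_SKIN_TEMPERATURE,
    store_history: bool = True,
    snapshot_every_ms: float | None = None,
    callbacks: Sequence[Callable[[float, float, np.ndarray], None]] = (),
) -> TemperatureField:
    """Run the cooling → pulse → rewarming timeline and collect the history.

    With ``store_history`` the full per-step history is retained (needed
    for post-hoc damage integration); otherwise only decimated snapshots
    (``snapshot_every_ms``) plus the running nodewise peak are kept, and
    any ``callbacks`` (e.g. a streaming damage accumulator) see every step.
    """
    times: list[float] = []
    history: list[np.ndarray] = []
    snaps: list[np.ndarray] = []
    snap_times: list[float] = []
    peak = None
    final = None
    next_snap = 0.0

    for t, dt, T in iterate_temperature(
        model,
        source,
        phases,
        pulse_start_ms,
        pulse_duration_ms,
        dt_pulse_ms,
        dt_cool_ms,
        dt_post_ms,
        t_initial,
    ):
        times.append(t)
        if peak is None:
            peak = T.copy()
        else:
            np.maximum(peak, T, out=peak)
        if store_history:
            history.append(T.copy())
        if snapshot_every_ms is not None and t * 1e3 >= next_snap - 1e-9:
            snaps.append(T.copy())
            snap_times.append(t)
            next_snap += snapshot_every_ms
        for cb in callbacks:
            cb(t, dt, T)
        final = T

    pulse_start = pulse_start_ms * 1e-3
    return TemperatureField(
        times=np.asarray(times),
        history=np.asarray(history) if store_history else None,
        snapshots=np.asarray(snaps) if snaps else None,
        snapshot_times=np.asarray(snap_times) if snap_times else None,
        final=final.copy(),
        peak=peak,
        pulse_start=pulse_start,
        pulse_end=pulse_start + pulse_duration_ms * 1e-3,
        model=model,
    )


def peak_temperature_map(field: TemperatureField) -> np.ndarray:
    """Nodewise maximum temperature over the run (deg C), initial state included."""
    return field.peak
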