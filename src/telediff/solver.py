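"""Explicit finite-difference integration of the telegraph-with-sink equation.

The equation

    tau * C_tt + gamma * C_t = D * Lap(C) - k * C

is advanced as the first-order system C_t = J, tau * J_t = D*Lap(C) - gamma*J
- k*C with a two-level explicit scheme, a 5-point (Cartesian) or conservative
3-point (radial) Laplacian, and zero-flux (mirror ghost) boundaries.  The
damping coefficient ``gamma`` is 1 for the physical model; other values are
used only by the exponential-decomposition consistency check.  ``tau = 0``
selects the parabolic branch gamma * C_t = D*Lap(C) - k*C explicitly, so the
closed-form diffusion oracle is reachable without a singular limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, List, Optional, Sequence

import numpy as np
from numba import njit

from .model import CenterTrace, Field, Grid, InitialCondition, TransportParams, build_field

__all__ = [
    "SolverConfig",
    "Solution",
    "step_bounds",
    "solve",
    "center_trace",
    "total_mass",
]


@dataclass
class SolverConfig:
    """Time-stepping and output configuration.

    ``dt_max`` caps the step below the stability bound; the default 0.5 s
    keeps the relaxation transient (tau ~ 1 s) temporally resolved.  Steps
    also shrink to land exactly on each save time, which is the adaptive
    part of the stepping.
    """

    save_times: Sequence[float] = dc_field(default_factory=lambda: np.arange(0.0, 601.0, 1.0))
    dt_max: float = 0.5
    safety: float = 0.4
    averaging_radius: float = 0.0
    negative_clip_tol: float = 1e-6
    damping: float = 1.0
    store_fields: bool = True

    def __post_init__(self) -> None:
        self.save_times = np.asarray(self.save_times, dtype=float)
        if self.save_times.ndim != 1 or self.save_times.size == 0:
            raise ValueError("save_times must be a non-empty 1-D sequence")
        if np.any(np.diff(self.save_times) <= 0):
            raise ValueError("save_times must be strictly increasing")
        if self.save_times[0] < 0:
            raise ValueError("save_times must be >= 0")
        if not (0 < self.safety < 1):
            raise ValueError("safety must lie in (0, 1)")
        if self.dt_max <= 0:
            raise ValueError("dt_max must be > 0")
        if self.damping <= 0:
            raise ValueError("damping must be > 0")


@dataclass
class Solution:
    """Solver output: saved fields, central trace and total mass vs time."""

    fields: List[Field]
    trace: CenterTrace
    mass: np.ndarray
    save_times: np.ndarray
    grid: Grid


def step_bounds(
    params: TransportParams,
    grid: Grid,
    safety: float = 0.4,
    dt_max: float = math.inf,
    damping: float = 1.0,
) -> float:
    """Largest stable explicit step: safety * min over the active limits.

    Active limits: the wave CFL spacing/sqrt(D/tau) when tau > 0 and D > 0;
    the diffusive bound spacing^2/(4D) on the tau = 0 branch; the damping
    bound 2*tau (divided by a non-unit damping coefficient); and 1/k when
    k > 0.  With no transport at all (D = tau = k = 0) returns ``dt_max``.
    """
    h = grid.spacing
    candidates = []
    if params.tau > 0:
        if params.D > 0:
            candidates.append(h / math.sqrt(params.D / params.tau))
        candidates.append(2.0 * params.tau / damping)
    elif params.D > 0:
        candidates.append(h * h / (4.0 * params.D))
    if params.k > 0:
        candidates.append(1.0 / params.k)
    if not candidates:
        return dt_max
    dt = safety * min(candidates)
    return min(dt, dt_max)


def _laplacian_cartesian(h: float) -> Callable[[np.ndarray], np.ndarray]:
    inv_h2 = 1.0 / (h * h)

    def lap(C: np.ndarray) -> np.ndarray:
        Cp = np.pad(C, 1, mode="edge")  # mirror ghost nodes -> zero flux
        return (
            Cp[:-2, 1:-1] + Cp[2:, 1:-1] + Cp[1:-1, :-2] + Cp[1:-1, 2:] - 4.0 * C
        ) * inv_h2

    return lap


@njit(cache=True)
def _radial_steps_hyperbolic(C, J, faces, inv_rh2, dt, nsteps, D, tau, k, gamma):
    # nsteps explicit Euler steps of the (C, J) system with the conservative
    # finite-volume form of (1/r) d/dr (r dC/dr) on cell centers; the r = 0
    # and outer faces carry zero flux, so the discrete mass sum telescopes.
    n = C.size
    lap = np.empty(n)
    for _ in range(nsteps):
        flux_prev = 0.0
        for j in range(n - 1):
            flux = faces[j] * (C[j + 1] - C[j])
            lap[j] = (flux - flux_prev) * inv_rh2[j]
            flux_prev = flux
        lap[n - 1] = -flux_prev * inv_rh2[n - 1]
        for j in range(n):
            c_new = C[j] + dt * J[j]
            J[j] += (dt / tau) * (D * lap[j] - gamma * J[j] - k * C[j])
            C[j] = c_new


@njit(cache=True)
def _radial_steps_parabolic(C, faces, inv_rh2, dt, nsteps, D, k, gamma):
    n = C.size
    lap = np.empty(n)
    for _ in range(nsteps):
        flux_prev = 0.0
        for j in range(n - 1):
            flux = faces[j] * (C[j + 1] - C[j])
            lap[j] = (flux - flux_prev) * inv_rh2[j]
            flux_prev = flux
        lap[n - 1] = -flux_prev * inv_rh2[n - 1]
        for j in range(n):
            C[j] += (dt / gamma) * (D * lap[j] - k * C[j])


def _center_mask(grid: Grid, averaging_radius: float) -> np.ndarray:
    if averaging_radius > grid.L / 2.0:
        raise ValueError(
            f"averaging_radius {averaging_radius} mm exceeds the half-domain {grid.L / 2} mm"
        )
    radii = grid.node_radii()
    if averaging_radius < grid.spacing:
        return radii <= radii.min() + 1e-12
    return radii <= averaging_radius


def total_mass(field: Field) -> float:
    """Total amount of substance: sum * h^2 (2D) or 2*pi*sum(v*r)*h (radial)."""
    g = field.grid
    h = g.spacing
    if g.geometry == "radial-1d":
        return float(2.0 * math.pi * np.sum(field.values * g.radial_coords()) * h)
    return float(np.sum(field.values) * h * h)


def solve(
    params: TransportParams,
    ic: InitialCondition,
    grid: Grid,
    cfg: SolverConfig,
    field0: Optional[Field] = None,
) -> Solution:
    """Integrate the transport equation and record state at ``cfg.save_times``.

    ``field0`` overrides the default at-rest initial field (used e.g. to
    start with a prescribed dC/dt).  Raises on numerical blow-up or on
    negative excursions beyond ``cfg.negative_clip_tol``.
    """
    state = field0.copy() if field0 is not None else build_field(ic, grid)
    if state.grid != grid:
        raise ValueError("field0 grid does not match the requested grid")
    C = state.values.copy()
    J = state.dvalues.copy()
    mask = _center_mask(grid, cfg.averaging_radius)

    dt_stable = step_bounds(params, grid, cfg.safety, cfg.dt_max, cfg.damping)
    dt_stable = min(dt_stable, cfg.dt_max)
    if not (dt_stable > 0 and np.isfinite(dt_stable)):
        raise ValueError(f"no positive stable time step obtainable (dt={dt_stable})")

    D, tau, k, gamma = params.D, params.tau, params.k, cfg.damping
    h_area = grid.spacing**2

    if grid.geometry == "radial-1d":
        h = grid.spacing
        r = grid.radial_coords()
        faces = np.arange(1, r.size) * h
        inv_rh2 = 1.0 / (r * h * h)

        if tau > 0:
            def advance(nsteps: int, dt: float) -> None:
                _radial_steps_hyperbolic(C, J, faces, inv_rh2, dt, nsteps, D, tau, k, gamma)
        else:
            def advance(nsteps: int, dt: float) -> None:
                _radial_steps_parabolic(C, faces, inv_rh2, dt, nsteps, D, k, gamma)
    else:
        lap = _laplacian_cartesian(grid.spacing)

        if tau > 0:
            def advance(nsteps: int, dt: float) -> None:
                nonlocal C, J
                for _ in range(nsteps):
                    L = lap(C)
                    C_new = C + dt * J
                    J += (dt / tau) * (D * L - gamma * J - k * C)
                    C = C_new
        else:
            def advance(nsteps: int, dt: float) -> None:
                nonlocal C
                for _ in range(nsteps):
                    C = C + (dt / gamma) * (D * lap(C) - k * C)

    save_times = cfg.save_times
    fields: List[Field] = []
    trace_vals = np.empty(save_times.size)
    mass = np.empty(save_times.size)

    t = float(state.t)
    i_save = 0

    def record(i: int) -> None:
        if not np.all(np.isfinite(C)):
            raise RuntimeError(
                f"solution became non-finite at t={t:.6g} s (dt={dt_stable:.6g} s)"
            )
        cmin = C.min()
        if cmin < -cfg.negative_clip_tol:
            raise RuntimeError(
                f"negative concentration {cmin:.3e} beyond tolerance at t={t:.6g} s"
            )
        trace_vals[i] = C[mask].mean()
        mass[i] = (
            2.0 * math.pi * np.sum(C * grid.radial_coords()) * grid.spacing
            if grid.geometry == "radial-1d"
            else np.sum(C) * h_area
        )
        if cfg.store_fields:
            fields.append(Field(C.copy(), J.copy(), t, grid))

    if save_times[0] <= t + 1e-12:
        record(0)
        i_save = 1

    for i in range(i_save, save_times.size):
        ts = save_times[i]
        span = ts - t
        if span > 1e-12:
            n_full = int(span // dt_stable)
            if n_full:
                advance(n_full, dt_stable)
                t += n_full * dt_stable
            rem = ts - t
            if rem > 1e-12:
                advance(1, rem)
            t = ts
        record(i)

    trace = CenterTrace(save_times.copy(), trace_vals, cfg.averaging_radius)
    return Solution(fields=fields, trace=trace, mass=mass, save_times=save_times.copy(), grid=grid)


def center_trace(sol: Solution, averaging_radius: float) -> CenterTrace:
    """Mean concentration over nodes with r <= averaging_radius, per saved field.

    Falls back to the nearest-to-center node(s) when the radius is below the
    grid spacing.
    """
    if averaging_radius < 0:
        raise ValueError("averaging_radius must be >= 0")
    if not sol.fields:
        raise ValueError("solution holds no stored fields; re-run with store_fields=True")
    mask = _center_mask(sol.grid, averaging_radius)
    times = np.array([f.t for f in sol.fields])
    values = np.array([f.values[mask].mean() for f in sol.fields])
    return CenterTrace(times, values, averaging_radius)
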