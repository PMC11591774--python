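"""Closed forms and diagnostics for the ballistic-to-diffusive crossover.

Central to the analysis is the rescaled relaxation coordinate

    u(t) = -1 / ln(1 - C(0, t) / C0(0)),

which is exactly linear in time, u = (4 D / R^2) t, when the central
concentration relaxes by normal 2-D diffusion from a uniform disk of radius
R.  Departure from linearity at early times diagnoses the wave-like
(relaxation-dominated) stage; the time at which the curve settles onto its
linear asymptote is the crossover time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .model import CenterTrace, InitialCondition, TransportParams

__all__ = [
    "RescaledTrace",
    "CrossoverResult",
    "rescale_relaxation",
    "disk_diffusion_center",
    "alpha_roots",
    "wave_speed",
    "asymptotic_slope",
    "crossover_time",
    "crossover_from_trace",
    "mass_ode_solution",
]

log = logging.getLogger(__name__)


@dataclass
class RescaledTrace:
    """The -1/ln(1 - C/C0) transform of a central trace.

    ``values`` is NaN where the transform is undefined (C >= C0 or C <= 0);
    ``valid_mask`` marks the defined points.  Invalid points are excluded
    from all downstream fits, never imputed.
    """

    times: np.ndarray
    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if not (self.times.shape == self.values.shape == self.valid_mask.shape):
            raise ValueError("times, values and valid_mask must share one shape")


@dataclass
class CrossoverResult:
    t_cross: float
    slope: float
    intercept: float
    window: Optional[Tuple[float, float]]
    tol: float


def rescale_relaxation(trace: CenterTrace, C0: float) -> RescaledTrace:
    """Apply u = -1/ln(1 - v/C0) elementwise, masking undefined points."""
    if C0 <= 0:
        raise ValueError("C0 must be > 0")
    v = trace.values
    valid = (v > 0) & (v < C0)
    values = np.full(v.shape, np.nan)
    x = 1.0 - v[valid] / C0
    values[valid] = -1.0 / np.log(x)
    if not valid.any():
        raise ValueError("rescaling is undefined at every point of the trace")
    return RescaledTrace(trace.times.copy(), values, valid)


def disk_diffusion_center(t, D: float, ic: InitialCondition) -> np.ndarray:
    """Central concentration for pure 2-D diffusion from a uniform disk.

    C(0, t) = C0 * (1 - exp(-R^2 / (4 D t))), with C(0, 0) = C0.  This is
    the closed-form oracle behind the linear rescaled coordinate.
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = np.full(t.shape, ic.C0)
    pos = t > 0
    out[pos] = ic.C0 * (1.0 - np.exp(-ic.R**2 / (4.0 * D * t[pos])))
    return out if out.shape else float(out)


def alpha_roots(params: TransportParams) -> Tuple[float, float]:
    """Roots of alpha*(tau*alpha - 1) = -k: (1 -+ sqrt(1 - 4*tau*k))/(2*tau).

    The smaller root (~k when 4*tau*k << 1) is the exponential rate that
    removes the sink term from the telegraph equation.  Returned smaller
    first; complex roots (4*tau*k > 1) are out of scope.
    """
    if params.tau <= 0:
        raise ValueError("alpha roots require tau > 0")
    disc = 1.0 - 4.0 * params.tau * params.k
    if disc < 0:
        raise ValueError("4*tau*k > 1: roots are complex, out of scope")
    root = math.sqrt(disc)
    a1 = (1.0 - root) / (2.0 * params.tau)
    a2 = (1.0 + root) / (2.0 * params.tau)
    return a1, a2


def wave_speed(params: TransportParams) -> float:
    """Finite propagation speed sqrt(D/tau) of the short-time wave-like stage, mm/s."""
    if params.tau <= 0:
        raise ValueError("wave speed is undefined (infinite) for tau = 0")
    return math.sqrt(params.D / params.tau)


def asymptotic_slope(
    rt: RescaledTrace, window: Tuple[float, float]
) -> Tuple[float, float]:
    """Ordinary least-squares line over the valid rescaled points in ``window``."""
    t_a, t_b = window
    sel = rt.valid_mask & (rt.times >= t_a) & (rt.times <= t_b)
    if sel.sum() < 3:
        raise ValueError(
            f"need >= 3 valid points in window [{t_a}, {t_b}], found {int(sel.sum())}"
        )
    slope, intercept = np.polyfit(rt.times[sel], rt.values[sel], 1)
    return float(slope), float(intercept)


def crossover_time(
    rt: RescaledTrace,
    asymptote: Tuple[float, float],
    tol: float = 0.05,
    window: Optional[Tuple[float, float]] = None,
) -> CrossoverResult:
    """Latest time the trace deviates from the asymptote by more than ``tol``.

    After this time the trace permanently stays within the relative
    tolerance band around the fitted line.  A trace within the band
    everywhere yields the first valid sample; a trace still outside the
    band at its final sample never settles and raises.
    """
    slope, intercept = asymptote
    if slope <= 0:
        raise ValueError("asymptote slope must be > 0")
    t = rt.times[rt.valid_mask]
    v = rt.values[rt.valid_mask]
    line = slope * t + intercept
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(v - line) / np.abs(line)
    rel[~np.isfinite(rel)] = np.inf  # line through zero counts as outside the band
    exceed = rel > tol
    if not exceed.any():
        t_cross = float(t[0])
    elif exceed[-1]:
        raise ValueError("trace never settles within the tolerance band")
    else:
        t_cross = float(t[np.nonzero(exceed)[0][-1]])
    return CrossoverResult(t_cross=t_cross, slope=slope, intercept=intercept,
                           window=window, tol=tol)


def crossover_from_trace(
    rt: RescaledTrace,
    window: Tuple[float, float] = (300.0, 600.0),
    tol: float = 0.05,
) -> CrossoverResult:
    """Fit the asymptote on ``window`` and locate the crossover time.

    Logs the sensitivity of the crossover to halving/doubling the tolerance,
    since the tolerance-band definition is a convention.
    """
    asym = asymptotic_slope(rt, window)
    res = crossover_time(rt, asym, tol=tol, window=window)
    for factor in (0.5, 2.0):
        try:
            alt = crossover_time(rt, asym, tol=tol * factor, window=window)
            log.info("crossover sensitivity: tol=%.3g -> t_cross=%.1f s", tol * factor, alt.t_cross)
        except ValueError:
            log.info("crossover sensitivity: tol=%.3g -> trace never settles", tol * factor)
    return res


def mass_ode_solution(t, params: TransportParams, M0: float) -> np.ndarray:
    """Closed form of tau*M'' + M' + k*M = 0 with M(0) = M0, M'(0) = 0.

    Under null-flux boundaries the spatial term of the transport equation
    integrates to zero, so the total mass obeys exactly this linear ODE.
    """
    t = np.asarray(t, dtype=float)
    if params.tau == 0:
        return M0 * np.exp(-params.k * t)
    if params.k == 0:
        return np.full(t.shape, float(M0))
    disc = 1.0 - 4.0 * params.tau * params.k
    if disc < 0:
        raise ValueError("oscillatory mass decay (4*tau*k > 1) is out of scope")
    if disc == 0:
        a = 1.0 / (2.0 * params.tau)
        return M0 * (1.0 + a * t) * np.exp(-a * t)
    a1, a2 = alpha_roots(params)
    return M0 * (a2 * np.exp(-a1 * t) - a1 * np.exp(-a2 * t)) / (a2 - a1)
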