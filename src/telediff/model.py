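"""Core data types: transport parameters, smoothed-disk initial condition, grids.

The physical picture is an axially symmetric marker spot (a dye-filled
microvessel channel of radius ``R``) releasing solute into a surrounding
porous medium.  Concentration is kept in normalized units (central value 1
at release), lengths in mm, time in s, with the spot center at the origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = [
    "TransportParams",
    "InitialCondition",
    "Grid",
    "Field",
    "CenterTrace",
    "initial_profile",
    "build_grid",
    "build_field",
]


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class TransportParams:
    """Coefficients of the telegraph-with-sink transport equation.

    tau * C_tt + C_t = D * Lap(C) - k * C

    Parameters
    ----------
    D : float
        Diffusion coefficient, mm^2/s.
    tau : float
        Relaxation time of the flux, s.  ``tau = 0`` selects the parabolic
        (pure diffusion-with-sink) branch.
    k : float
        First-order leakage/sink rate, 1/s (outflow into the bulk or
        trapping in pores).
    """

    D: float
    tau: float
    k: float

    def __post_init__(self) -> None:
        for name in ("D", "tau", "k"):
            v = _require_finite(name, getattr(self, name))
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class InitialCondition:
    """Smoothed disk of marker: C(r, 0) = (C0/2) * (1 + tanh((R^2 - r^2)/s)).

    ``s`` (mm^2) sets the sharpness of the decay from the plateau value
    ``C0`` to zero; the transition layer mimics the soaked perivascular
    collar around the channel.
    """

    C0: float = 1.0
    R: float = 0.9
    s: float = 0.44

    def __post_init__(self) -> None:
        for name in ("C0", "R", "s"):
            v = _require_finite(name, getattr(self, name))
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class Grid:
    """Equispaced cell-centered mesh on the square [-L/2, L/2]^2 (or its radius).

    ``geometry`` is ``"cartesian-2d"`` (N x N nodes) or ``"radial-1d"``
    (N//2 nodes spanning (0, L/2) by axial symmetry).  Spacing is L/N under
    the cell-centered convention.
    """

    L: float = 10.0
    N: int = 200
    geometry: str = "cartesian-2d"

    def __post_init__(self) -> None:
        L = _require_finite("L", self.L)
        if L <= 0:
            raise ValueError(f"L must be > 0, got {L}")
        if int(self.N) != self.N or self.N < 3:
            raise ValueError(f"N must be an integer >= 3, got {self.N}")
        if self.geometry not in ("cartesian-2d", "radial-1d"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        object.__setattr__(self, "L", L)
        object.__setattr__(self, "N", int(self.N))

    @property
    def spacing(self) -> float:
        return self.L / self.N

    def axis_coords(self) -> np.ndarray:
        """Cell-center coordinates along one Cartesian axis."""
        h = self.spacing
        return (np.arange(self.N) + 0.5) * h - self.L / 2.0

    def radial_coords(self) -> np.ndarray:
        """Cell-center radii for the radial-1d half domain, in (0, L/2)."""
        h = self.spacing
        return (np.arange(self.N // 2) + 0.5) * h

    def node_radii(self) -> np.ndarray:
        """Distance of every node from the spot center (the origin)."""
        if self.geometry == "radial-1d":
            return self.radial_coords()
        x = self.axis_coords()
        return np.hypot(x[:, None], x[None, :])

    @property
    def shape(self) -> Tuple[int, ...]:
        if self.geometry == "radial-1d":
            return (self.N // 2,)
        return (self.N, self.N)


@dataclass
class Field:
    """Discrete concentration state: values, their time derivative, and time."""

    values: np.ndarray
    dvalues: np.ndarray
    t: float
    grid: Grid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.dvalues = np.asarray(self.dvalues, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.dvalues.shape != self.values.shape:
            raise ValueError("dvalues shape must match values shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")

    def copy(self) -> "Field":
        return Field(self.values.copy(), self.dvalues.copy(), self.t, self.grid)


@dataclass
class CenterTrace:
    """Time series of the (averaged) central concentration."""

    times: np.ndarray
    values: np.ndarray
    averaging_radius: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def normalized(self) -> "CenterTrace":
        """Trace rescaled to unity at its first sample."""
        ref = self.values[0]
        if ref <= 0:
            raise ValueError("cannot normalize: first sample is non-positive")
        return CenterTrace(self.times.copy(), self.values / ref, self.averaging_radius)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_s": self.times, "value": self.values})


def initial_profile(r, ic: InitialCondition) -> np.ndarray:
    """Smoothed-disk radial profile (C0/2) * (1 + tanh((R^2 - r^2)/s)).

    Monotone non-increasing in r; equals exactly C0/2 at r = R.
    """
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("r must be finite")
    if np.any(r < 0):
        raise ValueError("r must be >= 0")
    return (ic.C0 / 2.0) * (1.0 + np.tanh((ic.R**2 - r**2) / ic.s))


def build_grid(L: float = 10.0, N: int = 200, geometry: str = "cartesian-2d") -> Grid:
    return Grid(L=L, N=N, geometry=geometry)


def build_field(ic: InitialCondition, grid: Grid) -> Field:
    """At-rest initial state: values from :func:`initial_profile`, dC/dt = 0.

    Warns when the mesh is too coarse to resolve the tanh transition layer
    (width ~ s / (2R)).
    """
    layer_width = ic.s / (2.0 * ic.R)
    if grid.spacing > layer_width:
        warnings.warn(
            f"grid spacing {grid.spacing:g} mm exceeds the initial transition-layer "
            f"width s/(2R) = {layer_width:g} mm; the profile edge is under-resolved",
            RuntimeWarning,
            stacklevel=2,
        )
    values = initial_profile(grid.node_radii(), ic)
    return Field(values=values, dvalues=np.zeros_like(values), t=0.0, grid=grid)
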