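"""Synthetic study data: central traces and 8-bit time-lapse image stacks.

Emulates the acquisition of an axially symmetric dark marker spot on a
lighter background: the forward model supplies the concentration field, a
linear optical mapping turns concentration into darkening (the dye is
treated as opaque within the 8-bit range), additive Gaussian noise and
quantization mimic the detector.  Every generator is deterministic given
its seed and records the ground truth it drew from, so the quantification
and fitting stages can be tested end to end without any recordings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .analytics import RescaledTrace
from .imaging import ImageStack, center_mean
from .model import CenterTrace, Grid, InitialCondition, TransportParams
from .solver import SolverConfig, solve

__all__ = [
    "AcquisitionSpec",
    "GroundTruth",
    "synth_center_trace",
    "synth_image_stack",
    "synth_breakpoint_trace",
    "ground_truth_center_trace",
]


@dataclass
class AcquisitionSpec:
    """Acquisition settings of the emulated recording.

    ``contrast`` is the grayscale drop per unit (normalized) concentration;
    with the default background level 200 and contrast 150 the spot center
    sits near level 54, comfortably inside the 8-bit range.
    """

    fps: float = 1.0
    duration: float = 600.0
    bit_depth: int = 8
    pixel_size: float = 0.01
    frame_shape: Optional[Tuple[int, int]] = None
    background_level: float = 200.0
    contrast: float = 150.0
    noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fps", "duration", "pixel_size", "background_level", "contrast"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class GroundTruth:
    """Generating parameters and the noiseless concentration behind a stack."""

    params: TransportParams
    ic: InitialCondition
    spec: AcquisitionSpec
    grid: Grid
    times: np.ndarray
    conc_frames: np.ndarray  # (T, H, W) noiseless concentration at pixel centers


def synth_center_trace(
    params: TransportParams,
    ic: InitialCondition,
    sampling_dt: float = 1.0,
    duration: float = 600.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    grid: Optional[Grid] = None,
    averaging_radius: float = 0.0,
) -> CenterTrace:
    """Normed central trace of the forward model plus optional iid Gaussian noise.

    The default 1-D radial grid matches the axisymmetric problem; the trace
    is normalized to unity at t = 0 before noise is added.
    """
    if sampling_dt <= 0 or duration <= 0:
        raise ValueError("sampling_dt and duration must be > 0")
    grid = grid or Grid(L=10.0, N=200, geometry="radial-1d")
    times = np.arange(0.0, duration + sampling_dt / 2, sampling_dt)
    cfg = SolverConfig(
        save_times=times, averaging_radius=averaging_radius, store_fields=False
    )
    sol = solve(params, ic, grid, cfg)
    values = sol.trace.values / sol.trace.values[0]
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sigma, size=values.shape)
    return CenterTrace(times, values, averaging_radius)


def _pixel_axes(spec: AcquisitionSpec, grid: Grid) -> Tuple[np.ndarray, np.ndarray]:
    if spec.frame_shape is None:
        n = int(round(grid.L / spec.pixel_size))
        shape = (n, n)
    else:
        shape = spec.frame_shape
    H, W = shape
    y = (np.arange(H) + 0.5 - H / 2.0) * spec.pixel_size
    x = (np.arange(W) + 0.5 - W / 2.0) * spec.pixel_size
    return y, x


def synth_image_stack(
    params: TransportParams,
    ic: InitialCondition,
    spec: AcquisitionSpec,
    grid: Optional[Grid] = None,
) -> Tuple[ImageStack, GroundTruth]:
    """Render the 2-D forward solution as an 8-bit time-lapse stack.

    Pixel level = clip(round(background - contrast * C + noise), 0, top);
    marker regions come out darker than the background.  Returns the stack
    together with the noiseless ground truth (concentration sampled at the
    pixel centers, plus the generating parameters).
    """
    grid = grid or Grid(L=10.0, N=200, geometry="cartesian-2d")
    if grid.geometry != "cartesian-2d":
        raise ValueError("image synthesis requires a cartesian-2d grid")
    frame_dt = 1.0 / spec.fps
    times = np.arange(0.0, spec.duration + frame_dt / 2, frame_dt)
    cfg = SolverConfig(save_times=times, store_fields=True)
    sol = solve(params, ic, grid, cfg)

    y, x = _pixel_axes(spec, grid)
    axis = grid.axis_coords()
    aligned = y.size == axis.size and x.size == axis.size and np.allclose(y, axis) and np.allclose(x, axis)

    top = 2**spec.bit_depth - 1
    rng = np.random.default_rng(spec.seed)
    conc = np.empty((times.size, y.size, x.size), dtype=np.float32)
    frames = np.empty_like(conc, dtype=np.uint8 if spec.bit_depth <= 8 else np.uint16)
    YY, XX = np.meshgrid(y, x, indexing="ij")
    pts = np.column_stack([YY.ravel(), XX.ravel()])
    for i, fld in enumerate(sol.fields):
        if aligned:
            c = fld.values
        else:
            interp = RegularGridInterpolator(
                (axis, axis), fld.values, bounds_error=False, fill_value=0.0
            )
            c = interp(pts).reshape(y.size, x.size)
        conc[i] = c
        level = spec.background_level - spec.contrast * c
        if spec.noise_sigma > 0:
            level = level + rng.normal(0.0, spec.noise_sigma, size=level.shape)
        frames[i] = np.clip(np.rint(level), 0, top).astype(frames.dtype)

    spot = conc[0] > 0.5 * ic.C0
    if spot.any():
        clipped = np.count_nonzero((frames == 0) & (conc > 0.5 * ic.C0)) / (
            np.count_nonzero(spot) * times.size
        )
        if clipped > 0.10:
            warnings.warn(
                f"contrast too large: {clipped:.0%} of spot pixels clipped to level 0",
                RuntimeWarning,
                stacklevel=2,
            )

    stack = ImageStack(
        frames=frames,
        pixel_size=spec.pixel_size,
        bit_depth=spec.bit_depth,
        timestamps=times.copy(),
        fps=spec.fps,
    )
    gt = GroundTruth(params=params, ic=ic, spec=spec, grid=grid, times=times.copy(),
                     conc_frames=conc)
    return stack, gt


def ground_truth_center_trace(gt: GroundTruth, n_pixels: int = 238) -> CenterTrace:
    """Normalized central trace of the noiseless ground truth.

    Applies the same nearest-``n_pixels``-disk averaging as the
    quantification chain, around the true (geometric) spot center.
    """
    H, W = gt.conc_frames.shape[1:]
    center = ((H - 1) / 2.0, (W - 1) / 2.0)
    vals = np.array([center_mean(c, center, n_pixels) for c in gt.conc_frames])
    return CenterTrace(gt.times.copy(), vals / vals[0],
                       averaging_radius=gt.spec.pixel_size * np.sqrt(n_pixels / np.pi))


def synth_breakpoint_trace(
    t_break: float,
    slope: float,
    intercept: float = 0.05,
    t_end: float = 600.0,
    dt: float = 1.0,
    rel_offset: float = 0.1,
    shape: str = "constant",
) -> RescaledTrace:
    """Piecewise fixture for crossover detection: linear after ``t_break``.

    Before the break the trace is the line scaled by (1 + offset), where the
    offset is ``rel_offset`` (constant) or ``rel_offset * (1 + ((t_break -
    t)/t_break)^2)/2`` >= rel_offset/2 (quadratic, still exceeding a band
    below rel_offset/2 everywhere).  With ``rel_offset`` at or below the
    detection tolerance the whole trace counts as settled.
    """
    if not (0 <= t_break <= t_end):
        raise ValueError("t_break must lie within [0, t_end]")
    times = np.arange(0.0, t_end + dt / 2, dt)
    line = slope * times + intercept
    pre = times < t_break
    if shape == "constant":
        offset = np.full(times.shape, rel_offset)
    elif shape == "quadratic":
        offset = rel_offset * (1.0 + ((t_break - times) / max(t_break, dt)) ** 2) / 2.0
    else:
        raise ValueError(f"unknown pre-break shape {shape!r}")
    values = np.where(pre, line * (1.0 + offset), line)
    return RescaledTrace(times=times, values=values, valid_mask=np.ones(times.shape, bool))
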