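"""Quantification of grayscale time-lapse stacks of a dark marker spot.

The chain mirrors how such recordings are reduced to concentration proxies:
the background is the mean grayscale far from the spot, every pixel is
subtracted from it (marker regions are darker, so they map to positive
values), intensities are averaged over a small disk of pixels around the
spot center, and everything is rescaled to unity at the initial central
value.  A squared-contrast pseudocolor enhancement is provided for
visualisation of faint leakage structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .model import CenterTrace

__all__ = [
    "ImageStack",
    "RadialProfile",
    "QuantificationResult",
    "corner_mask",
    "annulus_mask",
    "estimate_background",
    "subtract_invert",
    "find_center",
    "extract_cross_section",
    "center_mean",
    "normalize_stack",
    "pseudocolor_enhance",
    "quantify",
]


@dataclass
class ImageStack:
    """Timestamped grayscale frames (T, H, W) of integer levels."""

    frames: np.ndarray
    pixel_size: float
    bit_depth: int = 8
    timestamps: Optional[np.ndarray] = None
    fps: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        top = 2**self.bit_depth - 1
        if self.frames.min() < 0 or self.frames.max() > top:
            raise ValueError(f"levels must lie within [0, {top}]")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.timestamps is None:
            self.timestamps = np.arange(self.frames.shape[0]) / self.fps
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.shape != (self.frames.shape[0],):
            raise ValueError("one timestamp per frame required")
        if self.timestamps.size >= 2 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be increasing")

    @classmethod
    def from_tiff(cls, path: Union[str, Path], pixel_size: float, fps: float = 1.0,
                  bit_depth: int = 8) -> "ImageStack":
        import tifffile

        frames = tifffile.imread(str(path))
        if frames.ndim == 2:
            frames = frames[None]
        return cls(frames=frames, pixel_size=pixel_size, bit_depth=bit_depth, fps=fps)

    @classmethod
    def from_png_dir(cls, directory: Union[str, Path], pixel_size: float, fps: float = 1.0,
                     bit_depth: int = 8) -> "ImageStack":
        import imageio.v3 as iio

        paths = sorted(Path(directory).glob("*.png"))
        if not paths:
            raise FileNotFoundError(f"no .png frames in {directory}")
        frames = np.stack([iio.imread(p) for p in paths])
        return cls(frames=frames, pixel_size=pixel_size, bit_depth=bit_depth, fps=fps)

    def to_tiff(self, path: Union[str, Path]) -> None:
        import tifffile

        tifffile.imwrite(str(path), self.frames)


@dataclass
class RadialProfile:
    """Background-subtracted intensity along a diametral line (signed mm)."""

    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must share one shape")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be increasing")
        if np.any(self.values < 0):
            raise ValueError("profile values must be non-negative")


@dataclass
class QuantificationResult:
    trace: CenterTrace
    profiles: List[RadialProfile]
    background: float
    center: Tuple[float, float]
    n_center_pixels: int


def corner_mask(shape: Tuple[int, int], frac: float = 0.12) -> np.ndarray:
    """Boolean mask selecting four corner boxes of side frac*min(H, W)."""
    H, W = shape
    b = max(1, int(round(frac * min(H, W))))
    mask = np.zeros(shape, dtype=bool)
    mask[:b, :b] = mask[:b, -b:] = mask[-b:, :b] = mask[-b:, -b:] = True
    return mask


def annulus_mask(shape: Tuple[int, int], center: Tuple[float, float],
                 r_in: float, r_out: float) -> np.ndarray:
    """Boolean mask of pixels with r_in <= r <= r_out around ``center`` (px)."""
    rows, cols = np.indices(shape)
    r = np.hypot(rows - center[0], cols - center[1])
    return (r >= r_in) & (r <= r_out)


def estimate_background(frame: np.ndarray, region: np.ndarray) -> float:
    """Mean grayscale level over a spot-free region mask."""
    frame = np.asarray(frame)
    region = np.asarray(region, dtype=bool)
    if region.shape != frame.shape:
        raise ValueError("region mask must match the frame shape")
    if not region.any():
        raise ValueError("background region is empty")
    return float(frame[region].mean())


def subtract_invert(frame: np.ndarray, background: float) -> np.ndarray:
    """max(background - pixel, 0): darker marker pixels map to higher values.

    Pixels brighter than the background (noise) clip to zero so the
    concentration proxy stays non-negative.
    """
    return np.clip(background - np.asarray(frame, dtype=float), 0.0, None)


def find_center(map_: np.ndarray) -> Tuple[float, float]:
    """Intensity-weighted centroid (row, col) of a non-negative map."""
    m = np.asarray(map_, dtype=float)
    total = m.sum()
    if m.size == 0 or total <= 0:
        raise ValueError("cannot locate a center on an all-zero map")
    rows, cols = np.indices(m.shape)
    return (float((rows * m).sum() / total), float((cols * m).sum() / total))


def extract_cross_section(
    map_: np.ndarray,
    center: Tuple[float, float],
    pixel_size: float,
    halfwidth: int = 1,
) -> RadialProfile:
    """Horizontal diametral cross-section through ``center`` in mm coordinates.

    Averages over ``halfwidth`` rows on each side of the central row to tame
    single-row fluctuations.
    """
    m = np.asarray(map_, dtype=float)
    H, W = m.shape
    row = int(round(center[0]))
    if not (0 <= row < H and 0 <= center[1] < W):
        raise ValueError("center lies outside the frame")
    lo, hi = max(0, row - halfwidth), min(H, row + halfwidth + 1)
    values = m[lo:hi].mean(axis=0)
    positions = (np.arange(W) - center[1]) * pixel_size
    return RadialProfile(positions=positions, values=values)


def center_mean(map_: np.ndarray, center: Tuple[float, float], n_pixels: int = 238) -> float:
    """Mean over the ``n_pixels`` pixels nearest ``center`` (disk-ordered, ties by angle)."""
    m = np.asarray(map_, dtype=float)
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    if n_pixels > m.size:
        raise ValueError(f"n_pixels={n_pixels} exceeds the frame's {m.size} pixels")
    rows, cols = np.indices(m.shape)
    dy = rows - center[0]
    dx = cols - center[1]
    r2 = (dy * dy + dx * dx).ravel()
    theta = np.arctan2(dy, dx).ravel()
    order = np.lexsort((theta, np.round(r2, 9)))
    return float(m.ravel()[order[:n_pixels]].mean())


def normalize_stack(
    maps: Sequence[np.ndarray], center_values: Sequence[float]
) -> Tuple[List[np.ndarray], np.ndarray]:
    """Rescale maps and center values by the t = 0 central value (unity at start)."""
    center_values = np.asarray(center_values, dtype=float)
    ref = center_values[0]
    if ref <= 0:
        raise ValueError("reference central value at t = 0 must be > 0")
    return [np.asarray(m, dtype=float) / ref for m in maps], center_values / ref


def pseudocolor_enhance(frame: np.ndarray, background: float) -> np.ndarray:
    """Contrast enhancement (max(background - pixel, 0)/background)^2 in [0, 1].

    Squaring the normalized inverted level suppresses faint background
    fluctuations and highlights concentrated marker; mapping to an actual
    color table is left to the plotting layer.
    """
    if background <= 0:
        raise ValueError("background must be > 0")
    return (subtract_invert(frame, background) / background) ** 2


def quantify(
    stack: ImageStack,
    n_center: int = 238,
    background_region: Optional[np.ndarray] = None,
    halfwidth: int = 1,
    profile_stride: int = 1,
) -> QuantificationResult:
    """Full chain: background -> inversion -> centering -> normalized outputs.

    The background is averaged over a spot-free region (default: four corner
    boxes) across all frames; the spot center comes from the centroid of the
    first inverted frame; the trace is the nearest-``n_center``-pixel disk
    mean per frame, normalized to unity at the first frame.
    """
    frames = stack.frames
    region = corner_mask(frames.shape[1:]) if background_region is None else background_region
    background = float(
        np.mean([estimate_background(f, region) for f in frames])
    )
    maps = [subtract_invert(f, background) for f in frames]
    center = find_center(maps[0])
    centers = np.array([center_mean(m, center, n_center) for m in maps])
    norm_maps, trace_vals = normalize_stack(maps, centers)
    equiv_radius = stack.pixel_size * math.sqrt(n_center / math.pi)
    trace = CenterTrace(stack.timestamps.copy(), trace_vals, averaging_radius=equiv_radius)
    profiles = [
        extract_cross_section(m, center, stack.pixel_size, halfwidth=halfwidth)
        for m in norm_maps[::profile_stride]
    ]
    return QuantificationResult(
        trace=trace,
        profiles=profiles,
        background=background,
        center=center,
        n_center_pixels=n_center,
    )
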