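"""Speckle-contrast and flow-index computation (LASCA).

The speckle contrast K of a raw laser speckle image is the ratio of the
standard deviation of the intensity to its mean over a local window,

    K = sigma_I / <I>,

computed either spatially (a ``window x window`` neighbourhood around each
pixel) or temporally (a sliding window of frames at each pixel).  Motion of
scatterers (red blood cells) blurs the speckle during the camera exposure and
lowers K, so K maps inversely onto perfusion.  The flow index 1/K^2 is a
monotone, relative (arbitrary-unit) surrogate for flow velocity.

Conventions fixed here: the population standard deviation (K is an ensemble
quantity), symmetric reflection padding at image borders so the contrast map
has the shape of the input, and K = 0 wherever the local mean intensity is 0
(unlit background), so no division by zero ever occurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "RawFrame",
    "FrameStack",
    "ContrastImage",
    "FlowIndexImage",
    "spatial_contrast",
    "temporal_contrast",
    "flow_index",
    "render_contrast_map",
    "segment_background",
]

DEFAULT_WINDOW = 7
DEFAULT_K_FLOOR = 1e-3


@dataclass(frozen=True)
class RawFrame:
    """A single-channel raw speckle intensity image with acquisition metadata.

    ``pixels`` holds non-negative intensities as float64; ``exposure_ms`` is
    carried as metadata only (the contrast computation is exposure-agnostic).
    """

    pixels: np.ndarray
    bit_depth: int = 16
    exposure_ms: float = 5.0
    frame_index: int = 0
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("frame must be a non-empty 2-D intensity grid")
        if np.any(px < 0):
            raise ValueError("pixel intensities must be non-negative")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.exposure_ms <= 0:
            raise ValueError("exposure_ms must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class FrameStack:
    """An ordered sequence of equally shaped frames."""

    frames: tuple[RawFrame, ...]

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("frame stack is empty")
        shape = self.frames[0].shape
        if any(f.shape != shape for f in self.frames):
            raise ValueError("all frames in a stack must share one shape")
        object.__setattr__(self, "frames", tuple(self.frames))

    @classmethod
    def from_array(cls, cube: np.ndarray, **frame_kwargs) -> "FrameStack":
        cube = np.asarray(cube, dtype=np.float64)
        if cube.ndim != 3:
            raise ValueError("expected a (n_frames, rows, cols) array")
        return cls(
            tuple(
                RawFrame(cube[i], frame_index=i, **frame_kwargs)
                for i in range(cube.shape[0])
            )
        )

    def as_array(self) -> np.ndarray:
        return np.stack([f.pixels for f in self.frames])

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[RawFrame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> RawFrame:
        return self.frames[i]


@dataclass(frozen=True)
class ContrastImage:
    """Per-pixel speckle contrast K with the window it was computed over."""

    k_values: np.ndarray
    window: int
    method: Literal["spatial", "temporal"]

    def __post_init__(self) -> None:
        k = np.asarray(self.k_values, dtype=np.float64)
        if np.any(k < 0) or not np.all(np.isfinite(k)):
            raise ValueError("contrast values must be finite and >= 0")
        object.__setattr__(self, "k_values", k)

    @property
    def shape(self) -> tuple[int, int]:
        return self.k_values.shape


@dataclass(frozen=True)
class FlowIndexImage:
    """Relative flow map 1/K^2 in arbitrary units, clamped by ``k_floor``."""

    values: np.ndarray
    k_floor: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("flow-index values must be finite and positive")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _contrast_from_moments(mean: np.ndarray, mean_sq: np.ndarray) -> np.ndarray:
    # population variance; clip tiny negatives from floating-point cancellation
    var = np.clip(mean_sq - mean * mean, 0.0, None)
    k = np.zeros_like(mean)
    lit = mean > 0
    np.divide(np.sqrt(var), mean, out=k, where=lit)
    return k


def spatial_contrast(frame: RawFrame | np.ndarray, window: int = DEFAULT_WINDOW) -> ContrastImage:
    """Spatial speckle contrast K = sigma/mean over a sliding square window.

    Parameters
    ----------
    frame
        Raw speckle frame (or bare 2-D array).
    window
        Odd side length of the square neighbourhood, ``3 <= window <=
        min(rows, cols)``.  Borders use symmetric reflection padding so the
        output has the same shape as the input.

    Returns
    -------
    ContrastImage
        K map; K = 0 at pixels whose neighbourhood mean is 0.
    """
    if not isinstance(frame, RawFrame):
        frame = RawFrame(frame)
    rows, cols = frame.shape
    if window % 2 == 0 or window < 3 or window > min(rows, cols):
        raise ValueError(
            f"window must be odd and in [3, {min(rows, cols)}], got {window}"
        )
    px = frame.pixels
    # uniform_filter 'reflect' == numpy.pad 'symmetric' (edge pixel repeated)
    mean = ndimage.uniform_filter(px, size=window, mode="reflect")
    mean_sq = ndimage.uniform_filter(px * px, size=window, mode="reflect")
    return ContrastImage(_contrast_from_moments(mean, mean_sq), window, "spatial")


def temporal_contrast(stack: FrameStack | np.ndarray, depth: int = 10) -> list[ContrastImage]:
    """Temporal speckle contrast along the frame axis.

    K is computed per pixel over a sliding window of ``depth`` consecutive
    frames; one :class:`ContrastImage` is returned per window position
    (``len(stack) - depth + 1`` maps).
    """
    if not isinstance(stack, FrameStack):
        stack = FrameStack.from_array(np.asarray(stack))
    if depth < 2:
        raise ValueError("temporal window depth must be >= 2")
    if len(stack) < depth:
        raise ValueError(f"stack has {len(stack)} frames, fewer than depth={depth}")
    cube = stack.as_array()
    # cumulative sums along time give O(n) sliding moments
    csum = np.cumsum(cube, axis=0)
    csum_sq = np.cumsum(cube * cube, axis=0)
    zeros = np.zeros((1,) + cube.shape[1:])
    csum = np.concatenate([zeros, csum], axis=0)
    csum_sq = np.concatenate([zeros, csum_sq], axis=0)
    out: list[ContrastImage] = []
    for start in range(len(stack) - depth + 1):
        mean = (csum[start + depth] - csum[start]) / depth
        mean_sq = (csum_sq[start + depth] - csum_sq[start]) / depth
        out.append(
            ContrastImage(_contrast_from_moments(mean, mean_sq), depth, "temporal")
        )
    return out


def flow_index(contrast: ContrastImage, k_floor: float = DEFAULT_K_FLOOR) -> FlowIndexImage:
    """Relative flow index 1/max(K, k_floor)^2 (arbitrary units).

    The inverse-square relation links contrast to velocity only up to scale,
    so values are reported in AU; ``k_floor`` keeps the map finite where K
    vanishes (dark or perfectly static-free pixels).
    """
    if k_floor <= 0:
        raise ValueError("k_floor must be positive")
    k = np.maximum(contrast.k_values, k_floor)
    return FlowIndexImage(1.0 / (k * k), k_floor)


def render_contrast_map(
    contrast: ContrastImage,
    vmin: float = 0.0,
    vmax: float | None = None,
    k_floor: float = DEFAULT_K_FLOOR,
    cmap: str = "turbo",
) -> np.ndarray:
    """Render a contrast map as an 8-bit RGB flow image, blue -> red.

    The flow index 1/K^2 is linearly mapped onto a perceptually ordered
    blue-to-red colormap: high flow (low K) renders red, low flow (high K)
    renders blue.  Values are clipped to [vmin, vmax].

    Returns a ``(rows, cols, 3)`` uint8 array.
    """
    import matplotlib

    flow = flow_index(contrast, k_floor=k_floor).values
    if vmax is None:
        vmax = float(np.percentile(flow, 99.0))
    if not vmin < vmax:
        raise ValueError(f"vmin ({vmin}) must be < vmax ({vmax})")
    norm = np.clip((flow - vmin) / (vmax - vmin), 0.0, 1.0)
    colormap = matplotlib.colormaps[cmap]
    rgb = colormap(norm)[..., :3]
    return (rgb * 255).round().astype(np.uint8)


def segment_background(contrast: ContrastImage, threshold: float = 0.6) -> np.ndarray:
    """Threshold-segment static background from perfused tissue.

    A static, scattering background keeps fully developed speckle (K near 1)
    while perfused tissue is motion-blurred (K well below 1), so a simple
    threshold on K separates the two: the returned boolean mask is True where
    ``K > threshold`` (background), False over tissue (foreground is the
    complement).
    """
    return contrast.k_values > threshold
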