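"""Synthetic dynamic-speckle sequences with ground truth.

The forward model produces fully developed laser speckle: a circularly
symmetric complex Gaussian field, low-pass filtered to a controllable grain
size, whose pointwise intensity ``|field|^2`` is exponentially distributed —
hence a global contrast sigma/mean of 1 for a static scene.  Temporal
decorrelation (scatterer motion, i.e. flow) follows an AR(1) process on the
complex field,

    field' = rho * field + sqrt(1 - rho^2) * w,      rho = exp(-dt / tau),

which keeps the single-frame statistics exactly fully developed while the
decorrelation time ``tau`` plays the role of an inverse flow speed: short
tau = fast flow = strong blur over a finite exposure = low contrast.

A scene is composed of a perfused *tissue* region (short tau), optional
occluded *lesion* patches standing in for skin-mounted opaque patches that
block flow (long tau — the speckle there barely moves), and an optional dim
*static background* (a light-absorbing surface: little light but frozen
speckle, so K stays near 1).  Camera exposure is emulated by averaging M
sub-step intensity samples per frame, and rigid in-plane motion by shifting
the composited frame along a recorded trajectory (bilinear interpolation for
sub-pixel offsets).  Everything — frames, lesion centers, lesion masks — is
deterministic under the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from speckletrack.roi_geometry import (
    CircleRoi,
    Roi,
    circumscribed_bbox,
    roi_mask,
    translate_roi,
)
from speckletrack.speckle_core import FrameStack, RawFrame

__all__ = [
    "SimulationConfig",
    "SimulatedSequence",
    "synth_speckle_field",
    "evolve_field",
    "simulate_sequence",
    "constant_velocity_trajectory",
]


def _grain_transfer(shape: tuple[int, int], grain_sigma_px: float) -> np.ndarray:
    """Fourier transfer function of the grain filter, power-normalized.

    Filtering unit-variance complex white noise with this transfer yields a
    field with E|field|^2 = 1 exactly, for any grain size.
    """
    ky = np.fft.fftfreq(shape[0]) * 2.0 * np.pi
    kx = np.fft.fftfreq(shape[1]) * 2.0 * np.pi
    k2 = ky[:, None] ** 2 + kx[None, :] ** 2
    g = np.exp(-0.5 * grain_sigma_px**2 * k2)
    return g / np.sqrt(np.mean(g * g))


def synth_speckle_field(
    shape: tuple[int, int],
    grain_sigma_px: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw a fully developed complex speckle field of unit mean intensity.

    The field is circular complex Gaussian, spatially correlated at the
    grain scale; its intensity ``|field|^2`` is exponentially distributed at
    every pixel with mean 1 (so the global contrast of a static frame is 1).
    """
    if grain_sigma_px < 0:
        raise ValueError("grain_sigma_px must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = (
        rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    ) / np.sqrt(2.0)
    return np.fft.ifft2(np.fft.fft2(w) * _grain_transfer(shape, grain_sigma_px))


def evolve_field(
    field: np.ndarray,
    rho: float,
    grain_sigma_px: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One AR(1) decorrelation step of a complex speckle field.

    ``rho`` in [0, 1] is the field correlation over the step
    (``rho = exp(-dt/tau)``); innovation is an independent field with the
    same grain, so the stationary statistics are preserved exactly.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    if rho == 1.0:
        return field.copy()
    w = synth_speckle_field(field.shape, grain_sigma_px, seed)
    return rho * field + math.sqrt(1.0 - rho * rho) * w


def constant_velocity_trajectory(
    n_frames: int, vx: float, vy: float
) -> np.ndarray:
    """Per-frame absolute scene offsets for constant (vx, vy) px/frame motion."""
    t = np.arange(n_frames, dtype=np.float64)
    return np.stack([vx * t, vy * t], axis=1)


@dataclass(frozen=True)
class SimulationConfig:
    """Scene layout, dynamics and acquisition settings of a simulation.

    Decorrelation times are in units of the frame interval; ``None`` means
    static (rho = 1).  ``trajectory`` holds the absolute rigid offset (dx,
    dy) of the whole scene per frame, relative to the frame-0 layout;
    ``exposure_substeps`` (M) sub-exposures are averaged per frame to emulate
    motion blur of the speckle during a finite exposure.  The default pixel
    pitch of 1/40 cm/px reflects a ~20 x 15 cm field imaged at 1280 x 1024.
    """

    shape: tuple[int, int] = (256, 256)
    grain_sigma_px: float = 1.0
    tissue_tau: float | None = 0.1
    lesion_geometries: tuple[Roi, ...] = ()
    lesion_taus: tuple[float | None, ...] | None = None  # None: all static
    tissue_region: Roi | None = None  # None: tissue fills the frame
    background_level: float = 0.05  # intensity of the dim static background
    trajectory: np.ndarray | None = None  # (n_frames, 2); None: no motion
    n_frames: int = 1
    exposure_substeps: int = 8
    noise_sigma: float = 0.0  # additive Gaussian camera noise (intensity units)
    pixel_scale_cm: float = 1.0 / 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.exposure_substeps < 1:
            raise ValueError("exposure_substeps must be >= 1")
        if self.tissue_tau is not None and self.tissue_tau <= 0:
            raise ValueError("decorrelation times must be positive")
        taus = self.lesion_taus
        if taus is None:
            taus = tuple(None for _ in self.lesion_geometries)
        if len(taus) != len(self.lesion_geometries):
            raise ValueError("lesion_taus must match lesion_geometries")
        if any(t is not None and t <= 0 for t in taus):
            raise ValueError("decorrelation times must be positive")
        object.__setattr__(self, "lesion_taus", tuple(taus))
        traj = self.trajectory
        if traj is None:
            traj = np.zeros((self.n_frames, 2))
        traj = np.asarray(traj, dtype=np.float64)
        if traj.shape != (self.n_frames, 2):
            raise ValueError(
                f"trajectory must have shape ({self.n_frames}, 2), got {traj.shape}"
            )
        rows, cols = self.shape
        if np.any(np.abs(traj[:, 0]) >= cols) or np.any(np.abs(traj[:, 1]) >= rows):
            raise ValueError("trajectory pushes the scene fully out of frame")
        object.__setattr__(self, "trajectory", traj)


@dataclass(frozen=True)
class SimulatedSequence:
    """Frames plus full ground truth of a simulation run."""

    frames: FrameStack
    truth_centers: np.ndarray  # (n_frames, n_lesions, 2) as (cx, cy)
    lesion_masks: np.ndarray  # (n_frames, n_lesions, rows, cols) bool
    config: SimulationConfig

    def truth_roi(self, lesion: int, frame: int) -> Roi:
        """The lesion ROI at its ground-truth position in a given frame."""
        dx, dy = self.config.trajectory[frame]
        return translate_roi(self.config.lesion_geometries[lesion], dx, dy)


def _rho(tau: float | None, dt: float) -> float:
    if tau is None:
        return 1.0
    return math.exp(-dt / tau)


def _roi_center(roi: Roi) -> tuple[float, float]:
    if isinstance(roi, CircleRoi):
        return (roi.cx, roi.cy)
    return circumscribed_bbox(roi).center


def simulate_sequence(config: SimulationConfig) -> SimulatedSequence:
    """Run the forward model and return frames with ground truth.

    Per frame: each region's field is advanced by its AR(1) factor once per
    sub-exposure, the M sub-step intensities are composited (background under
    tissue under lesions) and averaged, optional camera noise is added, and
    the result is rigidly shifted to the frame's trajectory offset.  Lesion
    ground-truth centers and masks follow the same trajectory analytically.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.shape
    M = config.exposure_substeps
    dt_sub = 1.0 / M  # frame interval is the time unit

    tissue_field = synth_speckle_field(config.shape, config.grain_sigma_px, rng)
    lesion_fields = [
        synth_speckle_field(config.shape, config.grain_sigma_px, rng)
        for _ in config.lesion_geometries
    ]
    background_field = synth_speckle_field(config.shape, config.grain_sigma_px, rng)

    if config.tissue_region is None:
        tissue_mask0 = np.ones(config.shape, dtype=bool)
    else:
        tissue_mask0 = roi_mask(config.tissue_region, config.shape)
    lesion_masks0 = [roi_mask(g, config.shape) for g in config.lesion_geometries]

    rho_tis = _rho(config.tissue_tau, dt_sub)
    rho_les = [_rho(t, dt_sub) for t in config.lesion_taus]

    frames: list[RawFrame] = []
    truth_centers = np.zeros((config.n_frames, len(config.lesion_geometries), 2))
    lesion_masks = np.zeros(
        (config.n_frames, len(config.lesion_geometries), rows, cols), dtype=bool
    )
    centers0 = [_roi_center(g) for g in config.lesion_geometries]

    first_sample = True
    for t in range(config.n_frames):
        acc = np.zeros(config.shape)
        for _ in range(M):
            if not first_sample:
                tissue_field = evolve_field(
                    tissue_field, rho_tis, config.grain_sigma_px, rng
                )
                lesion_fields = [
                    evolve_field(f, r, config.grain_sigma_px, rng)
                    for f, r in zip(lesion_fields, rho_les)
                ]
            first_sample = False
            scene = np.full(
                config.shape,
                config.background_level,
                dtype=np.float64,
            ) * np.abs(background_field) ** 2
            scene[tissue_mask0] = np.abs(tissue_field[tissue_mask0]) ** 2
            for f, m in zip(lesion_fields, lesion_masks0):
                scene[m] = np.abs(f[m]) ** 2
            acc += scene
        frame = acc / M
        if config.noise_sigma > 0:
            frame = np.clip(
                frame + rng.normal(0.0, config.noise_sigma, size=frame.shape),
                0.0,
                None,
            )
        dx, dy = config.trajectory[t]
        if dx != 0.0 or dy != 0.0:
            # ndimage.shift moves content by +shift along (row, col);
            # periodic wrap so fresh speckle enters at the trailing edge
            # instead of a constant (zero-variance) replication band
            frame = ndimage.shift(frame, (dy, dx), order=1, mode="grid-wrap")
            frame = np.clip(frame, 0.0, None)
        frames.append(RawFrame(frame, frame_index=t, timestamp_s=float(t)))
        for j, geom in enumerate(config.lesion_geometries):
            truth_centers[t, j] = (centers0[j][0] + dx, centers0[j][1] + dy)
            lesion_masks[t, j] = roi_mask(translate_roi(geom, dx, dy), config.shape)

    return SimulatedSequence(
        frames=FrameStack(tuple(frames)),
        truth_centers=truth_centers,
        lesion_masks=lesion_masks,
        config=config,
    )
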