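"""Discriminative correlation filter (DCF) ROI tracking.

Tracks the circumscribed bounding box of an ROI from frame to frame with a
correlation filter in the Fourier domain, extended with the two reliability
ideas of the CSR-DCF family:

* **spatial reliability** — a foreground mask estimated from intensity
  histograms of the box interior vs. the surrounding ring restricts the
  filter to the object, suppressing boundary effects for non-rectangular
  targets;
* **channel reliability** — each feature channel (raw intensity, gradient
  magnitude, half-wave-rectified gradient components) carries its own filter,
  and channels are weighted by the quality of their individual responses.

The filter is trained on the first frame (MOSSE-style closed form with a
Gaussian target response) and adapted by exponential moving average.  The
box size is fixed for the whole run: only in-plane translation is estimated,
with sub-pixel refinement by a quadratic fit around the response peak.

ROI repositioning applies a displacement threshold: the ROI only moves when
the tracked center jumps by more than ``threshold_px`` (Euclidean), which
suppresses the sub-pixel jitter a correlation tracker exhibits even on a
perfectly static scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from speckletrack.roi_geometry import BoundingBox, Roi, translate_roi

__all__ = [
    "TrackerConfig",
    "TrackerState",
    "TrackResult",
    "init_tracker",
    "spatial_reliability_mask",
    "track_step",
    "roi_update",
]


@dataclass(frozen=True)
class TrackerConfig:
    """Hyperparameters of the correlation-filter tracker.

    ``learning_rate`` is the EMA factor for filter adaptation, ``reg_lambda``
    the ridge regularizer of the closed-form filter, ``padding`` the template
    size as a multiple of the bounding box, ``sigma_factor`` sets the width
    of the Gaussian target response relative to the box diagonal,
    ``search_radius_px`` caps the per-frame displacement (None: template/3),
    and ``peak_floor`` is the response level below which the target is
    declared lost (box held and flagged rather than moved).
    """

    learning_rate: float = 0.02
    reg_lambda: float = 0.01
    padding: float = 2.0
    sigma_factor: float = 0.1
    search_radius_px: float | None = None
    peak_floor: float = 0.05
    displacement_threshold_px: float = 1.0
    use_spatial_mask: bool = True
    use_channel_weights: bool = True


@dataclass
class TrackerState:
    """Everything the tracker carries between frames."""

    filters_num: np.ndarray  # (n_ch, H, W) complex: EMA of G* . conj(Fhat_c)
    filters_den: np.ndarray  # (n_ch, H, W) real: EMA of |Fhat_c|^2
    channel_weights: np.ndarray  # (n_ch,) non-negative, sums to 1
    spatial_mask: np.ndarray  # (H, W) soft mask over the template
    template_size: tuple[int, int]  # (H, W) of the padded template
    bbox_size: tuple[float, float]  # fixed (w, h) of the tracked box
    last_center: tuple[float, float]  # (cx, cy), sub-pixel
    config: TrackerConfig = field(default_factory=TrackerConfig)

    @property
    def last_bbox(self) -> BoundingBox:
        w, h = self.bbox_size
        cx, cy = self.last_center
        return BoundingBox(cx - w / 2.0, cy - h / 2.0, w, h)


@dataclass(frozen=True)
class TrackResult:
    """Outcome of one tracking step."""

    bbox: BoundingBox
    center: tuple[float, float]
    response_peak: float
    lost: bool = False
    moved: bool = False


# ---------------------------------------------------------------------------
# feature extraction


def _extract_patch(
    image: np.ndarray, center: tuple[float, float], size: tuple[int, int]
) -> np.ndarray:
    """Bilinear patch extraction at a sub-pixel center, reflecting at borders."""
    H, W = size
    cx, cy = center
    xs = cx + (np.arange(W) - (W - 1) / 2.0)
    ys = cy + (np.arange(H) - (H - 1) / 2.0)
    coords = np.meshgrid(ys, xs, indexing="ij")
    return ndimage.map_coordinates(
        image.astype(np.float64), coords, order=1, mode="reflect"
    )


def _feature_channels(patch: np.ndarray) -> np.ndarray:
    """Stack of feature channels for a grayscale patch.

    Channels: normalized intensity, gradient magnitude, and the four
    half-wave-rectified gradient components (a cheap 4-bin orientation code
    suited to monochrome speckle/contrast images).
    """
    p = patch - patch.mean()
    std = patch.std()
    if std > 0:
        p = p / std
    gy, gx = np.gradient(p)
    mag = np.hypot(gx, gy)
    chans = np.stack(
        [
            p,
            mag,
            np.maximum(gx, 0.0),
            np.maximum(-gx, 0.0),
            np.maximum(gy, 0.0),
            np.maximum(-gy, 0.0),
        ]
    )
    # zero-mean each channel so the filter keys on structure, not DC level
    return chans - chans.mean(axis=(1, 2), keepdims=True)


def _hann2d(size: tuple[int, int]) -> np.ndarray:
    H, W = size
    return np.outer(np.hanning(H), np.hanning(W))


def _gaussian_response(size: tuple[int, int], sigma: float) -> np.ndarray:
    H, W = size
    yy, xx = np.mgrid[0:H, 0:W]
    g = np.exp(
        -0.5 * (((yy - (H - 1) / 2.0) ** 2 + (xx - (W - 1) / 2.0) ** 2) / sigma**2)
    )
    return g


# ---------------------------------------------------------------------------
# spatial reliability


def spatial_reliability_mask(
    patch: np.ndarray,
    bbox_in_patch: BoundingBox,
    n_bins: int = 32,
    min_coverage: float = 0.25,
) -> np.ndarray:
    """Foreground-probability mask for the template from intensity histograms.

    The box interior provides the foreground intensity model and the
    surrounding ring the background model; per-pixel posterior foreground
    probability is binarized at 0.5 and regularized (morphological closing,
    largest connected component, slight blur).  If the result covers less
    than ``min_coverage`` of the box area — indistinguishable histograms or
    a uniform patch — the fall-back is an all-ones mask over the box.
    """
    patch = np.asarray(patch, dtype=np.float64)
    H, W = patch.shape
    yy, xx = np.mgrid[0:H, 0:W]
    inner = (
        (xx >= bbox_in_patch.x)
        & (xx < bbox_in_patch.x + bbox_in_patch.w)
        & (yy >= bbox_in_patch.y)
        & (yy < bbox_in_patch.y + bbox_in_patch.h)
    )
    box_mask = inner.astype(np.float64)
    lo, hi = patch.min(), patch.max()
    if hi - lo <= 1e-12:
        return _soften(box_mask)
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(patch, edges) - 1, 0, n_bins - 1)
    hf = np.bincount(idx[inner].ravel(), minlength=n_bins).astype(np.float64)
    hb = np.bincount(idx[~inner].ravel(), minlength=n_bins).astype(np.float64)
    hf /= max(hf.sum(), 1.0)
    hb /= max(hb.sum(), 1.0)
    post = hf[idx] / (hf[idx] + hb[idx] + 1e-12)
    mask = (post > 0.5) & inner
    mask = ndimage.binary_closing(mask, iterations=2)
    lbl, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
        mask = lbl == (1 + int(np.argmax(sizes)))
    if mask.sum() < min_coverage * inner.sum():
        return _soften(box_mask)
    return _soften(mask.astype(np.float64))


def _soften(mask: np.ndarray) -> np.ndarray:
    return ndimage.gaussian_filter(mask, sigma=1.0)


# ---------------------------------------------------------------------------
# training / tracking


def _train_terms(
    chans: np.ndarray, g_hat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    f_hat = np.fft.fft2(chans, axes=(-2, -1))
    num = np.conj(f_hat) * g_hat  # so that response(F) = ifft(num/(den+l) * F)
    den = (f_hat * np.conj(f_hat)).real
    return num, den


def _windowed_features(
    image: np.ndarray,
    center: tuple[float, float],
    size: tuple[int, int],
    mask: np.ndarray,
) -> np.ndarray:
    patch = _extract_patch(image, center, size)
    chans = _feature_channels(patch)
    return chans * (_hann2d(size) * mask)


def _channel_responses(state: TrackerState, chans: np.ndarray) -> np.ndarray:
    f_hat = np.fft.fft2(chans, axes=(-2, -1))
    filt = state.filters_num / (state.filters_den + state.config.reg_lambda)
    return np.fft.ifft2(filt * f_hat, axes=(-2, -1)).real


def init_tracker(
    image: np.ndarray, bbox: BoundingBox, config: TrackerConfig | None = None
) -> TrackerState:
    """Train a correlation filter on the first frame's bounding box.

    The returned state self-detects: running :func:`track_step` on the same
    frame relocates the center to within a fraction of a pixel.

    Raises ``ValueError`` for a degenerate (textureless) template or a box
    outside the image.
    """
    config = config or TrackerConfig()
    image = np.asarray(image, dtype=np.float64)
    rows, cols = image.shape
    if bbox.w * bbox.h < 16:
        raise ValueError("bounding box area must be at least 16 px")
    if (
        bbox.x + bbox.w <= 0
        or bbox.y + bbox.h <= 0
        or bbox.x >= cols
        or bbox.y >= rows
    ):
        raise ValueError("bounding box lies outside the image")
    H = max(16, int(round(bbox.h * config.padding)))
    W = max(16, int(round(bbox.w * config.padding)))
    center = bbox.center
    patch = _extract_patch(image, center, (H, W))
    if patch.std() < 1e-9:
        raise ValueError("degenerate template: patch has no texture to track")

    bbox_in_patch = BoundingBox(
        (W - 1) / 2.0 - bbox.w / 2.0, (H - 1) / 2.0 - bbox.h / 2.0, bbox.w, bbox.h
    )
    if config.use_spatial_mask:
        mask = spatial_reliability_mask(patch, bbox_in_patch)
    else:
        mask = np.ones((H, W))

    sigma = config.sigma_factor * np.sqrt(bbox.w * bbox.h)
    g_hat = np.fft.fft2(_gaussian_response((H, W), sigma))
    chans = _feature_channels(patch) * (_hann2d((H, W)) * mask)
    num, den = _train_terms(chans, g_hat)

    state = TrackerState(
        filters_num=num,
        filters_den=den,
        channel_weights=np.full(chans.shape[0], 1.0 / chans.shape[0]),
        spatial_mask=mask,
        template_size=(H, W),
        bbox_size=(bbox.w, bbox.h),
        last_center=center,
        config=config,
    )
    # channel reliability from the training frame's own responses
    state.channel_weights = _reestimate_weights(state, _channel_responses(state, chans))
    return state


def _reestimate_weights(state: TrackerState, responses: np.ndarray) -> np.ndarray:
    if not state.config.use_channel_weights:
        return np.full(responses.shape[0], 1.0 / responses.shape[0])
    peaks = responses.reshape(responses.shape[0], -1).max(axis=1)
    w = np.clip(peaks, 0.0, None)
    total = w.sum()
    if total <= 0:
        return np.full(responses.shape[0], 1.0 / responses.shape[0])
    return w / total


def _subpixel_offset(resp: np.ndarray, py: int, px: int) -> tuple[float, float]:
    """Quadratic (parabola) refinement of a response peak, one axis at a time."""
    H, W = resp.shape

    def refine(vm: float, v0: float, vp: float) -> float:
        denom = vm - 2.0 * v0 + vp
        if denom >= -1e-12:
            return 0.0
        off = 0.5 * (vm - vp) / denom
        return float(np.clip(off, -0.5, 0.5))

    dy = refine(resp[(py - 1) % H, px], resp[py, px], resp[(py + 1) % H, px])
    dx = refine(resp[py, (px - 1) % W], resp[py, px], resp[py, (px + 1) % W])
    return dx, dy


def track_step(state: TrackerState, image: np.ndarray) -> tuple[TrackerState, TrackResult]:
    """Locate the target in a new frame and adapt the filter.

    The channel-weighted correlation response is evaluated over the template
    centered on the last known position; the displacement is the response
    peak offset (sub-pixel, capped at the search radius).  On success the
    filters and channel weights are EMA-updated from the new location; when
    the peak falls below ``peak_floor`` the target is flagged lost and the
    box is held in place with no model update.
    """
    image = np.asarray(image, dtype=np.float64)
    cfg = state.config
    H, W = state.template_size
    chans = _windowed_features(image, state.last_center, (H, W), state.spatial_mask)
    responses = _channel_responses(state, chans)
    resp = np.tensordot(state.channel_weights, responses, axes=1)

    radius = cfg.search_radius_px
    if radius is None:
        radius = min(H, W) / 3.0
    # response is circular: displacement d appears at center + d (mod size)
    cy0, cx0 = (H - 1) / 2.0, (W - 1) / 2.0
    yy, xx = np.mgrid[0:H, 0:W]
    dyg = (yy - cy0 + H / 2.0) % H - H / 2.0
    dxg = (xx - cx0 + W / 2.0) % W - W / 2.0
    in_window = dyg**2 + dxg**2 <= radius**2
    masked = np.where(in_window, resp, -np.inf)
    py, px = np.unravel_index(int(np.argmax(masked)), resp.shape)
    peak = float(resp[py, px])

    if peak < cfg.peak_floor:
        result = TrackResult(
            bbox=state.last_bbox,
            center=state.last_center,
            response_peak=peak,
            lost=True,
        )
        return state, result

    sx, sy = _subpixel_offset(resp, py, px)
    dx = dxg[py, px] + sx
    dy = dyg[py, px] + sy
    norm = float(np.hypot(dx, dy))
    if norm > radius:
        dx *= radius / norm
        dy *= radius / norm
    new_center = (state.last_center[0] + dx, state.last_center[1] + dy)

    # adapt the model at the new location
    sigma = cfg.sigma_factor * np.sqrt(state.bbox_size[0] * state.bbox_size[1])
    g_hat = np.fft.fft2(_gaussian_response((H, W), sigma))
    new_chans = _windowed_features(image, new_center, (H, W), state.spatial_mask)
    num_new, den_new = _train_terms(new_chans, g_hat)
    lr = cfg.learning_rate
    new_state = replace(
        state,
        filters_num=(1 - lr) * state.filters_num + lr * num_new,
        filters_den=(1 - lr) * state.filters_den + lr * den_new,
        channel_weights=(1 - lr) * state.channel_weights
        + lr * _reestimate_weights(state, responses),
        last_center=new_center,
    )
    result = TrackResult(
        bbox=new_state.last_bbox,
        center=new_center,
        response_peak=peak,
        lost=False,
    )
    return new_state, result


def roi_update(
    roi: Roi,
    prev_center: tuple[float, float],
    new_center: tuple[float, float],
    threshold_px: float = 1.0,
) -> tuple[Roi, bool]:
    """Move the ROI only when the tracked center displacement is significant.

    If the Euclidean displacement between the previous and new box centers
    exceeds ``threshold_px`` the ROI is translated by that displacement and
    ``moved=True`` is returned; otherwise the ROI is returned unchanged
    (``moved=False``), treating sub-threshold motion as tracker jitter.
    """
    if threshold_px < 0:
        raise ValueError("threshold_px must be >= 0")
    dx = new_center[0] - prev_center[0]
    dy = new_center[1] - prev_center[1]
    if float(np.hypot(dx, dy)) > threshold_px:
        return translate_roi(roi, dx, dy), True
    return roi, False
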