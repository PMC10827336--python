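"""End-to-end orchestration: frames -> contrast -> tracking -> traces -> ICC.

The per-frame processing order mirrors the acquisition pipeline of an LSCI
system with ROI tracking: the speckle-contrast image is computed first, the
tracker then locates each ROI's bounding box on it (or on the raw frame,
per config), the displacement-threshold rule decides whether the ROI
actually moves, and the perfusion value — the mean flow index inside the
current ROI, scaled to arbitrary units — is appended to that ROI's trace.

``run_agreement_experiment`` replicates the manual-vs-automatic comparison
on simulator output: the "manual" arm repositions each ROI from the
simulator's ground-truth trajectory in every frame (an idealized assessor),
the automatic arm runs the tracker from a first-frame initialization only,
and the two traces are compared with the two-way random ICC.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from speckletrack.dcf_tracker import (
    TrackerConfig,
    init_tracker,
    roi_update,
    track_step,
)
from speckletrack.reliability_stats import IccResult, PerfusionTrace, icc_two_way
from speckletrack.roi_geometry import (
    CircleRoi,
    PolygonRoi,
    Roi,
    circumscribed_bbox,
    roi_mask,
    translate_roi,
)
from speckletrack.speckle_core import (
    ContrastImage,
    FrameStack,
    flow_index,
    render_contrast_map,
    spatial_contrast,
)
from speckletrack.speckle_simulator import SimulatedSequence, SimulationConfig, simulate_sequence

logger = logging.getLogger("speckletrack.pipeline")

__all__ = [
    "RunConfig",
    "ExperimentResult",
    "process_sequence",
    "run_agreement_experiment",
    "read_stack",
    "write_outputs",
    "roi_from_dict",
    "roi_to_dict",
]


@dataclass(frozen=True)
class RunConfig:
    """Processing settings for a sequence run.

    ``au_scale`` maps the dimensionless flow index 1/K^2 onto arbitrary
    perfusion units; ``track_on`` selects the tracker's input image
    ("contrast" — lesions are visible there — or "raw"); ``trace_on``
    selects the traced quantity ("flow" or "contrast").
    """

    contrast_window: int = 7
    tracking: bool = True
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    displacement_threshold_px: float = 1.0
    k_floor: float = 1e-3
    au_scale: float = 100.0
    track_on: str = "contrast"  # "contrast" | "raw"
    trace_on: str = "flow"  # "flow" | "contrast"
    filter_window: int = 1  # moving-average window applied to traces (1 = off)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.track_on not in ("contrast", "raw"):
            raise ValueError("track_on must be 'contrast' or 'raw'")
        if self.trace_on not in ("flow", "contrast"):
            raise ValueError("trace_on must be 'flow' or 'contrast'")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class ExperimentResult:
    """Traces, trajectories and agreement statistics of one run."""

    auto_traces: dict[str, PerfusionTrace]
    manual_traces: dict[str, PerfusionTrace]
    trajectories: pd.DataFrame
    icc: dict[str, IccResult]
    config: RunConfig
    config_hash: str
    contrast_preview: ContrastImage | None = None

    def paired_matrix(self, roi_id: str) -> np.ndarray:
        """(n_frames, 2) matrix of (manual, auto) values for one ROI."""
        manual = self.manual_traces[roi_id].values
        auto = self.auto_traces[roi_id].values
        if len(manual) != len(auto):
            raise ValueError("manual and auto traces differ in length")
        return np.stack([manual, auto], axis=1)


def _maybe_filter(trace: PerfusionTrace, config: RunConfig) -> PerfusionTrace:
    if config.filter_window > 1:
        from speckletrack.reliability_stats import moving_average

        return moving_average(trace, config.filter_window)
    return trace


def _mask_mean(image: np.ndarray, roi: Roi) -> float:
    mask = roi_mask(roi, image.shape)
    if not mask.any():
        raise ValueError(f"ROI {roi.id!r} left the image entirely")
    return float(image[mask].mean())


def process_sequence(
    frames: FrameStack,
    rois: list[Roi],
    config: RunConfig | None = None,
) -> ExperimentResult:
    """Run the automatic analysis branch over a frame stack.

    For every frame, in order: compute the spatial contrast image; if
    tracking is enabled, advance each ROI's correlation-filter tracker and
    apply the displacement-threshold update; record the mean traced value
    (flow index in AU by default) inside the ROI at its current position.
    With tracking off, every ROI stays at its initial coordinates.

    ROIs must lie inside the first frame; a mid-run lost target is flagged
    in the trajectory table and the run continues with the box held.
    """
    config = config or RunConfig()
    if len(frames) < 1:
        raise ValueError("need at least one frame")
    shape = frames.shape
    for roi in rois:
        if not roi_mask(roi, shape).any():
            raise ValueError(f"ROI {roi.id!r} lies outside frame 0")

    current = {roi.id: roi for roi in rois}
    trackers: dict[str, object] = {}
    traces: dict[str, list[float]] = {roi.id: [] for roi in rois}
    rows: list[dict] = []
    preview: ContrastImage | None = None

    for t, frame in enumerate(frames):
        contrast = spatial_contrast(frame, config.contrast_window)
        if preview is None:
            preview = contrast
        logger.debug("frame %d: contrast computed before tracking", t)
        flow = flow_index(contrast, config.k_floor)
        track_image = contrast.k_values if config.track_on == "contrast" else frame.pixels
        trace_image = (
            config.au_scale * flow.values
            if config.trace_on == "flow"
            else contrast.k_values
        )
        for roi0 in rois:
            rid = roi0.id
            roi = current[rid]
            moved = False
            lost = False
            peak = np.nan
            if config.tracking:
                if t == 0:
                    trackers[rid] = init_tracker(
                        track_image, circumscribed_bbox(roi), config.tracker
                    )
                else:
                    state = trackers[rid]
                    prev_center = circumscribed_bbox(roi).center
                    state, result = track_step(state, track_image)
                    trackers[rid] = state
                    peak = result.response_peak
                    lost = result.lost
                    if not lost:
                        roi, moved = roi_update(
                            roi,
                            prev_center,
                            result.center,
                            config.displacement_threshold_px,
                        )
                        current[rid] = roi
            traces[rid].append(_mask_mean(trace_image, roi))
            cx, cy = circumscribed_bbox(roi).center
            rows.append(
                dict(
                    frame=t,
                    roi_id=rid,
                    cx=cx,
                    cy=cy,
                    moved=moved,
                    response_peak=peak,
                    lost=lost,
                )
            )

    idx = np.arange(len(frames))
    auto = {
        rid: _maybe_filter(
            PerfusionTrace(rid, np.asarray(v), idx, source="auto"), config
        )
        for rid, v in traces.items()
    }
    return ExperimentResult(
        auto_traces=auto,
        manual_traces={},
        trajectories=pd.DataFrame(rows),
        icc={},
        config=config,
        config_hash=config.config_hash(),
        contrast_preview=preview,
    )


def reference_traces(
    sequence: SimulatedSequence,
    rois: list[Roi],
    config: RunConfig,
) -> dict[str, PerfusionTrace]:
    """Ground-truth-repositioned ("manual") traces for simulator output.

    Each ROI is translated by the scene's true trajectory in every frame —
    the idealization of an assessor who re-draws the ROI on the lesion in
    each frame — and the same traced quantity as the automatic branch is
    extracted.
    """
    out: dict[str, list[float]] = {roi.id: [] for roi in rois}
    for t, frame in enumerate(sequence.frames):
        contrast = spatial_contrast(frame, config.contrast_window)
        trace_image = (
            config.au_scale * flow_index(contrast, config.k_floor).values
            if config.trace_on == "flow"
            else contrast.k_values
        )
        dx, dy = sequence.config.trajectory[t]
        for roi in rois:
            out[roi.id].append(_mask_mean(trace_image, translate_roi(roi, dx, dy)))
    idx = np.arange(len(sequence.frames))
    return {
        rid: _maybe_filter(
            PerfusionTrace(rid, np.asarray(v), idx, source="manual"), config
        )
        for rid, v in out.items()
    }


def run_agreement_experiment(
    sim_config: SimulationConfig,
    run_config: RunConfig | None = None,
    rois: list[Roi] | None = None,
) -> ExperimentResult:
    """Manual-vs-automatic agreement experiment on a simulated sequence.

    Generates the sequence, extracts reference traces from ground-truth ROI
    positions, runs the automatic branch (tracker initialized on frame 0
    only), and computes the two-way random ICC per ROI on the paired traces.
    By default the analysis ROIs are the lesion geometries themselves.
    """
    run_config = run_config or RunConfig()
    sequence = simulate_sequence(sim_config)
    if rois is None:
        rois = list(sim_config.lesion_geometries)
    if not rois:
        raise ValueError("agreement experiment needs at least one ROI")
    result = process_sequence(sequence.frames, rois, run_config)
    result.manual_traces = reference_traces(sequence, rois, run_config)
    for roi in rois:
        result.icc[roi.id] = icc_two_way(result.paired_matrix(roi.id))
    return result


# ---------------------------------------------------------------------------
# I/O

_FRAME_SUFFIXES = (".png", ".pgm", ".tif", ".tiff")


def read_stack(path: str | Path) -> FrameStack:
    """Read a frame stack from a multi-page TIFF or a directory of images.

    Directory frames are ordered lexicographically by filename; all frames
    must share one shape and dtype.
    """
    import tifffile

    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
        )
        if not files:
            raise ValueError(f"no frame images found in directory {path}")
        import imageio.v3 as iio

        arrays = [np.asarray(iio.imread(f)) for f in files]
        shapes = {a.shape for a in arrays}
        dtypes = {a.dtype for a in arrays}
        if len(shapes) > 1 or len(dtypes) > 1:
            raise ValueError(
                f"frames in {path} have mixed shapes {shapes} or dtypes {dtypes}"
            )
        cube = np.stack(arrays)
    elif path.is_file():
        cube = tifffile.imread(path)
        if cube.ndim == 2:
            cube = cube[None]
    else:
        raise IOError(f"no such file or directory: {path}")
    if cube.ndim != 3:
        raise ValueError(f"expected single-channel frames, got shape {cube.shape}")
    bit_depth = 8 if cube.dtype == np.uint8 else 16
    return FrameStack.from_array(cube.astype(np.float64), bit_depth=bit_depth)


def write_stack(stack: FrameStack, path: str | Path, gain: float = 10000.0) -> None:
    """Write a frame stack as a 16-bit multi-page TIFF (``gain`` counts/unit)."""
    import tifffile

    cube = np.clip(stack.as_array() * gain, 0, 65535).astype(np.uint16)
    tifffile.imwrite(Path(path), cube)


def write_outputs(result: ExperimentResult, out_dir: str | Path) -> dict[str, Path]:
    """Write traces, trajectories, ICC report, preview PNG and config.

    Returns a mapping of artifact name to path; every CSV carries the config
    hash in a header comment for provenance.
    """
    import imageio.v3 as iio
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _write_csv(df: pd.DataFrame, name: str) -> None:
        p = out / name
        with open(p, "w") as fh:
            fh.write(f"# config_hash={result.config_hash}\n")
            df.to_csv(fh, index=False)
        written[name] = p

    trace_rows = []
    for source, traces in (
        ("auto", result.auto_traces),
        ("manual", result.manual_traces),
    ):
        for rid, tr in traces.items():
            for f, v in zip(tr.frame_indices, tr.values):
                trace_rows.append(dict(frame=int(f), roi_id=rid, source=source, value=v))
    _write_csv(pd.DataFrame(trace_rows), "traces.csv")
    _write_csv(result.trajectories, "trajectories.csv")

    if result.icc:
        icc_rows = [
            dict(
                roi_id=rid,
                icc=r.icc,
                sigma_b2=r.sigma_b2,
                sigma_w2=r.sigma_w2,
                n_targets=r.n_targets,
                k_raters=r.k_raters,
                category=r.category,
            )
            for rid, r in result.icc.items()
        ]
        _write_csv(pd.DataFrame(icc_rows), "icc_report.csv")

    if result.contrast_preview is not None:
        rgb = render_contrast_map(result.contrast_preview)
        p = out / "contrast_preview.png"
        iio.imwrite(p, rgb)
        written["contrast_preview.png"] = p

    p = out / "run_config.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump(
            dict(config_hash=result.config_hash, **asdict(result.config)), fh
        )
    written["run_config.yaml"] = p
    return written


def roi_from_dict(d: dict) -> Roi:
    """Build an ROI from the JSON/YAML schema {id, shape, center|vertices, radius}."""
    shape = d.get("shape")
    if shape == "circle":
        cx, cy = d["center"]
        return CircleRoi(cx=float(cx), cy=float(cy), r=float(d["radius"]), id=str(d.get("id", "C1")))
    if shape == "polygon":
        return PolygonRoi(
            vertices=tuple((float(x), float(y)) for x, y in d["vertices"]),
            id=str(d.get("id", "R1")),
        )
    raise ValueError(f"unknown ROI shape {shape!r}")


def roi_to_dict(roi: Roi) -> dict:
    if isinstance(roi, CircleRoi):
        return dict(id=roi.id, shape="circle", center=[roi.cx, roi.cy], radius=roi.r)
    if isinstance(roi, PolygonRoi):
        return dict(id=roi.id, shape="polygon", vertices=[list(v) for v in roi.vertices])
    raise TypeError(f"not an ROI: {roi!r}")
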