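"""Canonical simulation scenarios for validating the tracking pipeline.

Two scenarios bracket the regimes the manual-vs-automatic agreement
experiment is designed to probe:

* **slow** — a 1 x 2 cm occluded rectangle (the larger lesion geometry)
  drifting at ~2 px/frame through perfused tissue.  The tracker follows
  easily and agreement with ground-truth repositioning is excellent.
* **fast** — a 1-cm occluded circle (the small lesion) at the scene edge
  over the dark static background, moving at 15 px/frame against a tracker
  search radius of 10 px.  The correlation filter cannot jump farther than
  its search window per frame, so it lags and loses the lesion — the
  characteristic fast-motion failure of bounding-box trackers — and the
  agreement collapses.

Geometry uses the default pixel pitch of 1/40 cm/px, so the 1-cm-diameter
circle has r = 20 px and the 1 x 2 cm rectangle is 40 x 80 px.
"""

from __future__ import annotations

from speckletrack.dcf_tracker import TrackerConfig
from speckletrack.pipeline import RunConfig
from speckletrack.roi_geometry import CircleRoi, PolygonRoi
from speckletrack.speckle_simulator import (
    SimulationConfig,
    constant_velocity_trajectory,
)

__all__ = ["slow_scenario", "fast_scenario"]

PX_PER_CM = 40.0


def slow_scenario(
    seed: int = 0, n_frames: int = 50
) -> tuple[SimulationConfig, RunConfig]:
    """Slow-motion rectangle-lesion scenario (the paper-style easy regime).

    A 40 x 80 px (1 x 2 cm) occluded rectangle moves at (2, 0.5) px/frame
    through fast-decorrelating tissue filling a 256 x 256 scene.
    """
    rect = PolygonRoi(((60, 90), (140, 90), (140, 130), (60, 130)), id="R1")
    sim = SimulationConfig(
        shape=(256, 256),
        tissue_tau=0.1,
        lesion_geometries=(rect,),
        trajectory=constant_velocity_trajectory(n_frames, 2.0, 0.5),
        n_frames=n_frames,
        exposure_substeps=8,
        pixel_scale_cm=1.0 / PX_PER_CM,
        seed=seed,
    )
    return sim, RunConfig()


def fast_scenario(
    seed: int = 0, n_frames: int = 12
) -> tuple[SimulationConfig, RunConfig]:
    """Fast-motion small-circle scenario (the degraded regime).

    A 1-cm circle (r = 20 px) sits in a narrow tissue band at the scene
    edge, with the dark static background below, and moves at 15 px/frame —
    beyond the 10 px per-frame search radius configured for the tracker, so
    the tracker lags and the ROI is left behind over background.
    """
    circ = CircleRoi(50, 40, 20, id="C1")
    tissue = PolygonRoi(((0, 10), (256, 10), (256, 70), (0, 70)), id="tissue")
    sim = SimulationConfig(
        shape=(256, 256),
        tissue_tau=0.1,
        lesion_geometries=(circ,),
        tissue_region=tissue,
        trajectory=constant_velocity_trajectory(n_frames, 15.0, 0.0),
        n_frames=n_frames,
        exposure_substeps=8,
        pixel_scale_cm=1.0 / PX_PER_CM,
        seed=seed,
    )
    run = RunConfig(tracker=TrackerConfig(search_radius_px=10.0))
    return sim, run
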