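# Methods

## Speckle contrast and flow index

The contrast map is `K = σ/μ` with the *population* standard deviation —
K is an ensemble definition, and fixing the estimator makes the brute-force
oracle comparison exact. Spatial estimation (default window 7×7, a common
LASCA choice; configurable, odd, ≥3) is the default because it needs only
one frame and therefore preserves temporal resolution; temporal estimation
over a sliding depth of frames is also provided. Borders use symmetric
reflection padding so the K map has the source frame's shape and ROIs near
borders remain analyzable. Windows with zero mean (unlit background) define
K = 0 rather than dividing by zero.

The flow index is `1/max(K, k_floor)²` with `k_floor = 1e-3`; the
inverse-square law links contrast to velocity only up to an unknown
proportionality, so flow is reported in arbitrary units and the pipeline's
`au_scale` (default 100) merely places typical tissue values in a
convenient few-hundred-AU range. Rendering maps the flow index linearly
onto the perceptually ordered blue→red `turbo` colormap (high flow red,
low flow blue). Background segmentation thresholds K directly: a static
scattering surface keeps K ≈ 1 while perfused tissue sits well below, so
`K > 0.6` (default) flags background.

## ROI geometry

Coordinates are 0-based with x = column, y = row, and pixel centers at
integers; membership is boundary-inclusive on pixel centers. ROI positions
are real-valued: the tracker emits sub-pixel centers and masks are
re-rasterized from the analytic geometry every frame, so rounding error
cannot accumulate along a trajectory. Areas are analytic (πr², shoelace)
times the squared pixel pitch; the default pitch of 1/40 cm/px reflects a
~20 × 15 cm field of view on a 1280 × 1024 sensor, making the standard
lesion patches a 40 px-diameter circle (0.785 cm²) and a 40 × 80 px
rectangle (2 cm²).

## Tracker

A discriminative correlation filter in the Fourier domain (MOSSE-style
closed form against a Gaussian target response, σ = 0.1·√(w·h)), extended
with the two reliability mechanisms of the CSR-DCF family:

* a **spatial reliability mask** from foreground/background intensity
  histograms (32 bins; box interior vs. padding ring; posterior binarized
  at 0.5, morphologically closed, largest component kept, softened). If the
  mask covers under 25 % of the box — indistinguishable histograms — the
  fall-back is the full box.
* **channel reliability** weights over six feature channels: normalized
  intensity, gradient magnitude, and four half-wave-rectified gradient
  components (a cheap orientation code suited to monochrome imagery).
  Weights are re-estimated from per-channel response peaks and smoothed
  with the same learning rate as the filters.

Defaults: learning rate 0.02, regularization λ = 0.01, template padding 2×
the box, cosine (Hann) window, search radius template/3 unless configured.
The box size is fixed for the whole run — only in-plane translation is
estimated, with sub-pixel refinement by a 1-D quadratic fit per axis around
the response peak. A response peak below `peak_floor` (0.05; self-detection
peaks near 1) flags the target lost: the box is held and the frame marked,
never silently re-anchored. The tracker may run on the contrast image
(default — occluded lesions are high-contrast objects there and the
pipeline computes contrast before tracking anyway) or on the raw frame.

The ROI moves only when the tracked center is displaced by more than
`displacement_threshold_px` (default 1.0 px Euclidean — the smallest value
that suppresses sub-pixel jitter) from the ROI's last *accepted* position.
Comparing against the accepted position rather than the immediately
preceding frame keeps zero-mean jitter suppressed exactly while still
following arbitrarily slow real drift, which a frame-to-frame comparison
would ignore forever.

## Simulator

Fully developed speckle is synthesized as a circularly symmetric complex
Gaussian field, low-pass filtered in the Fourier domain to a grain scale
(`grain_sigma_px`, default 1) with an analytically power-normalized
transfer function, so pointwise intensity is exactly exponential with mean
1 and a static frame has global contrast 1. Temporal decorrelation is an
AR(1) process on the *field* (not the intensity), `f' = ρf + √(1−ρ²)w`
with `ρ = exp(−dt/τ)`, which preserves the single-frame statistics exactly;
τ is the per-region decorrelation time in units of the frame interval and
stands in for inverse flow speed.

A scene composites a dim static background (intensity 0.05 — a
light-absorbing surface still shows frozen speckle, so its K stays near 1),
perfused tissue (default τ = 0.1 frame intervals), and occluded lesion
patches (static by default) whose geometry mirrors the standard 1-cm circle
and 1 × 2 cm rectangle at 40 px/cm. Exposure blur is emulated by averaging
M sub-step intensities per frame (default M = 8); rigid in-plane motion
shifts the composited frame by the per-frame absolute trajectory offset
with bilinear interpolation and periodic wrap, so fresh speckle enters at
the trailing edge instead of a zero-variance replication band (which would
clamp the flow index at its ceiling). Ground-truth lesion centers and masks
follow the same trajectory analytically. Everything is deterministic under
the configured seed.

What the simulator does *not* emulate: physical scattering calibration
(absolute velocities), sensor noise beyond optional additive Gaussian
noise, non-rigid deformation, rotation/scale changes, illumination drift,
and motion blur *within* a sub-step. Passing tests therefore demonstrate
algorithmic correctness under the stated forward model, not clinical
performance on real recordings.

## Agreement statistics

The ICC is the two-way random-effects, absolute-agreement, single-measure
form ICC(2,1), computed from two-way ANOVA mean squares; the variance
components reported satisfy `ICC = σ_B²/(σ_B² + σ_W²)` with σ_W²
aggregating rater and residual variance (components are clipped at zero,
so the identity is approximate only when a component estimate is negative,
i.e. near-zero true ICC). Single-measure absolute agreement is the standard
choice for method comparison; the frames of a recording are the targets and
the two analysis methods the raters, paired per frame. Banding assigns
boundary values to the upper category (0.75 → good). A zero-variance matrix
raises rather than returning a conventional value. The motion-artifact
filter is a centered moving average (default window 5, odd, symmetric
reflection at the ends); other filter families are out of scope.

## Validation scenarios

`scenarios.slow_scenario` (1 × 2 cm rectangle lesion, (2, 0.5) px/frame,
50 frames, 256² scene) is the trackable regime; agreement between
ground-truth repositioning and tracking lands in the excellent band.
`scenarios.fast_scenario` (1-cm circle in a narrow tissue band at the scene
edge over dark background, 15 px/frame, tracker search radius 10 px) is the
failure regime: a correlation tracker cannot jump farther than its search
window per frame, so it lags, loses the lesion, and agreement collapses —
the characteristic small-fast-target degradation of bounding-box trackers.
The "manual" arm of every agreement experiment is the simulator's ground
truth (an idealized assessor who repositions the ROI perfectly every
frame); real manual annotation is out of scope.

Problem sizes used by the test suite and the acceptance script (256² scenes,
≤50 frames, 64² oracle frames, 500 × 4 ICC recovery matrices) were chosen so
the full validation runs in about a minute on one CPU while keeping every
statistical check comfortably powered.

## Known limitations

* Flow is relative (AU); no multi-exposure or absolute calibration.
* No rotation/scale adaptation of the box; out-of-plane motion and
  deformation are untracked.
* Temporal contrast assumes aligned frames; it is not motion-compensated.
* The ICC is estimated per frame pair over a whole recording; no
  downsampling or autocorrelation correction is applied, so frames are
  treated as exchangeable targets.
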