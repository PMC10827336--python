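"""Agreement statistics for perfusion traces.

Manual-vs-automatic agreement is quantified with the intraclass correlation
coefficient under a two-way random-effects model: frames are the targets,
the two analysis methods are the raters, and

    rho = sigma_B^2 / (sigma_B^2 + sigma_W^2),

with sigma_B^2 the between-target (true perfusion) variance and sigma_W^2
the unwanted within-target variance (rater plus residual).  The estimator is
the single-measure absolute-agreement form ICC(2,1) computed from the
two-way ANOVA mean squares,

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E)),

which equals the variance-ratio expression above with
sigma_B^2 = (MS_R - MS_E)/k and sigma_W^2 = (MS_C - MS_E)/n + MS_E.

Reliability is banded in the conventional way: below 0.5 poor, 0.5-0.75
moderate, 0.75-0.9 good, 0.9 and above excellent (boundaries owned by the
upper band).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PerfusionTrace",
    "IccResult",
    "icc_two_way",
    "classify_reliability",
    "moving_average",
]


@dataclass(frozen=True)
class PerfusionTrace:
    """Per-frame mean ROI intensity (arbitrary units) for one ROI."""

    roi_id: str
    values: np.ndarray
    frame_indices: np.ndarray
    source: str = "auto"  # "manual" | "auto"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        idx = np.asarray(self.frame_indices, dtype=np.int64)
        if v.shape != idx.shape or v.ndim != 1:
            raise ValueError("values and frame_indices must be equal-length 1-D")
        if len(idx) > 1 and np.any(np.diff(idx) <= 0):
            raise ValueError("frame_indices must be strictly increasing")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "frame_indices", idx)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class IccResult:
    """ICC estimate with its variance components and reliability band."""

    icc: float
    sigma_b2: float
    sigma_w2: float
    n_targets: int
    k_raters: int
    category: str


def icc_two_way(data: np.ndarray) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Parameters
    ----------
    data
        ``(n_targets, k_raters)`` matrix with no missing cells; here rows
        are frames and columns the analysis methods being compared.

    Raises
    ------
    ValueError
        For fewer than 3 targets or 2 raters, or when the matrix has zero
        total variance (the ICC is undefined).
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("data must be a 2-D (targets x raters) matrix")
    n, k = data.shape
    if n < 3 or k < 2:
        raise ValueError(f"need >= 3 targets and >= 2 raters, got {n} x {k}")
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains non-finite cells")

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = float(((data - grand) ** 2).sum())
    if ss_total <= 1e-12 * max(1.0, grand * grand) * n * k:
        raise ValueError("zero total variance: ICC is undefined")
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols

    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))

    icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e))
    sigma_b2 = max((ms_r - ms_e) / k, 0.0)
    sigma_w2 = max((ms_c - ms_e) / n, 0.0) + ms_e
    return IccResult(
        icc=float(icc),
        sigma_b2=sigma_b2,
        sigma_w2=sigma_w2,
        n_targets=n,
        k_raters=k,
        category=classify_reliability(float(icc)),
    )


def classify_reliability(icc: float) -> str:
    """Band an ICC value: poor / moderate / good / excellent.

    Cut points 0.5, 0.75 and 0.9; each boundary belongs to the upper band.
    """
    if icc > 1.0 + 1e-9:
        raise ValueError(f"ICC cannot exceed 1, got {icc}")
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def moving_average(trace: PerfusionTrace, w: int = 5) -> PerfusionTrace:
    """Centered moving-average filter for motion-artifact suppression.

    Window ``w`` must be odd; ends are handled by symmetric reflection so
    the output length equals the input length.  ``w = 1`` is the identity.
    Short spikes (bulk-motion artifacts) are spread and attenuated while the
    slow perfusion signal passes through.
    """
    n = len(trace)
    if w % 2 == 0 or w < 1 or w > n:
        raise ValueError(f"window must be odd and in [1, {n}], got {w}")
    if w == 1:
        return trace
    half = w // 2
    padded = np.pad(trace.values, half, mode="symmetric")
    kernel = np.full(w, 1.0 / w)
    smoothed = np.convolve(padded, kernel, mode="valid")
    return PerfusionTrace(
        roi_id=trace.roi_id,
        values=smoothed,
        frame_indices=trace.frame_indices,
        source=trace.source,
    )
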