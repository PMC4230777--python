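"""Ca2+ imaging preprocessing: ROIs, baselines, spikes, glial traces.

Converts a fluorescence movie (or raw per-ROI traces) into the binary
spike trains and z-scored continuous glial traces the model consumes:

1. ROI detection -- local maxima of the temporally averaged, spatially
   Gaussian-smoothed image, with a minimum separation between centres;
2. trace extraction -- mean intensity over the ROI's pixels per frame;
3. baseline estimation -- iterative inlier reselection: points within one
   SD of the current baseline are inliers, the baseline is rebuilt by
   linear interpolation through them (constant extrapolation at the ends),
   and the SD is recomputed, until convergence.  This doubles as
   detrending (e.g. photobleaching);
4. spike detection -- local maxima of the residual exceeding a threshold
   in baseline-SD units, one spike per bin;
5. glial traces -- linear detrend, temporal Gaussian smoothing, z-score.

Whether an ROI is a neuron or a glial cell is user-supplied metadata; it
is not inferred here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.ndimage
import scipy.signal

__all__ = [
    "ImageStack",
    "ROI",
    "RawTrace",
    "BaselineDecomposition",
    "detect_rois",
    "extract_trace",
    "estimate_baseline",
    "detect_spikes",
    "preprocess_glia_trace",
]


@dataclass
class ImageStack:
    """Time-lapse fluorescence movie: (time, rows, cols) intensities."""

    frames: np.ndarray
    frame_interval: float
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("need a (time, rows, cols) stack with >= 2 frames")
        if not np.isfinite(self.frames).all():
            raise ValueError("stack intensities must be finite")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class ROI:
    """Circular region of interest; centre and radius in micrometers."""

    id: int
    center: tuple[float, float]  # (x, y) = (col, row) * pixel_size
    radius: float
    kind: str = "neuron"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")
        if self.kind not in ("neuron", "glia"):
            raise ValueError("ROI kind must be 'neuron' or 'glia'")


@dataclass
class RawTrace:
    values: np.ndarray
    roi_id: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or not np.isfinite(self.values).all():
            raise ValueError("trace must be a finite 1D array")


@dataclass
class BaselineDecomposition:
    """Exact split trace = baseline + residual, with the final inlier SD."""

    baseline: np.ndarray
    residual: np.ndarray
    sd: float
    n_iterations: int
    inliers: np.ndarray  # final inlier mask over timepoints


def _local_maxima_2d(img: np.ndarray, radius_px: int) -> list[tuple[int, int]]:
    """Strict local maxima within a disk; plateaus yield the lowest-index pixel."""
    yy, xx = np.mgrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    footprint = (yy**2 + xx**2) <= radius_px**2
    maxfilt = scipy.ndimage.maximum_filter(img, footprint=footprint,
                                           mode="nearest")
    flat = img == maxfilt
    labels, n = scipy.ndimage.label(flat)
    peaks = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        # plateau spanning the whole neighborhood = constant region, skip
        # unless it is a genuine isolated maximum
        order = np.lexsort((cols, rows))
        peaks.append((int(rows[order[0]]), int(cols[order[0]])))
    return peaks


def detect_rois(
    stack: ImageStack,
    smooth_sigma: float,
    roi_radius: float = 3.0,
    min_separation: float = 6.0,
    threshold_rel: float = 0.05,
) -> list[ROI]:
    """ROIs at local maxima of the smoothed temporal-mean image.

    ``smooth_sigma``, ``roi_radius`` and ``min_separation`` are in
    micrometers.  Peaks must rise at least ``threshold_rel`` of the image
    range above the minimum, which suppresses the flat-background plateau.
    Deterministic: maxima are ranked by intensity (ties by row-major pixel
    index) and greedily accepted subject to the separation.
    """
    if smooth_sigma <= 0:
        raise ValueError("smooth_sigma must be positive")
    mean_img = stack.frames.mean(axis=0)
    if np.ptp(mean_img) == 0.0:
        raise ValueError("constant stack has no intensity maxima")
    px = stack.pixel_size
    smoothed = scipy.ndimage.gaussian_filter(mean_img, sigma=smooth_sigma / px)
    sep_px = max(int(np.ceil(min_separation / px)), 1)
    floor = smoothed.min() + threshold_rel * np.ptp(smoothed)
    peaks = [rc for rc in _local_maxima_2d(smoothed, sep_px)
             if smoothed[rc] > floor]
    if not peaks:
        raise ValueError("no local maxima found in the smoothed mean image")
    peaks.sort(key=lambda rc: (-smoothed[rc], rc))
    accepted: list[tuple[int, int]] = []
    for r, c in peaks:
        if all((r - r0) ** 2 + (c - c0) ** 2 >= sep_px**2 for r0, c0 in accepted):
            accepted.append((r, c))
    return [
        ROI(id=k, center=(c * px, r * px), radius=roi_radius)
        for k, (r, c) in enumerate(accepted)
    ]


def _roi_pixel_mask(stack: ImageStack, roi: ROI) -> np.ndarray:
    px = stack.pixel_size
    rows, cols = stack.frames.shape[1:]
    yy, xx = np.mgrid[0:rows, 0:cols]
    cx, cy = roi.center
    return ((xx * px - cx) ** 2 + (yy * px - cy) ** 2) <= roi.radius**2


def extract_trace(stack: ImageStack, roi: ROI) -> RawTrace:
    """Mean intensity over the ROI's pixels at each frame."""
    mask = _roi_pixel_mask(stack, roi)
    if not mask.any():
        raise ValueError(f"ROI {roi.id} covers no pixels")
    return RawTrace(stack.frames[:, mask].mean(axis=1), roi.id)


def estimate_baseline(
    trace: RawTrace | np.ndarray,
    max_iter: int = 50,
    tol: Optional[float] = None,
) -> BaselineDecomposition:
    """Iterative inlier-interpolation baseline (detrending) of a trace.

    Start from a flat baseline at the trace mean; repeatedly mark timepoints
    within one SD of the current baseline as inliers, rebuild the baseline
    by linear interpolation through the inliers (constant extrapolation at
    the ends), and recompute the SD from the new residual, until the
    maximum baseline change falls below ``tol`` (default 1e-6 x trace SD).
    """
    values = trace.values if isinstance(trace, RawTrace) else np.asarray(trace, float)
    if len(values) < 3:
        raise ValueError("need at least 3 timepoints")
    trace_sd = float(values.std())
    tol = 1e-6 * trace_sd if tol is None else tol
    t = np.arange(len(values), dtype=float)
    baseline = np.full_like(values, values.mean())
    sd = max(trace_sd, np.finfo(float).tiny)
    inliers = np.ones(len(values), bool)
    iterations = 0
    for iterations in range(1, max_iter + 1):
        resid = values - baseline
        inliers = np.abs(resid) <= sd
        if not inliers.any():
            raise RuntimeError(
                f"baseline estimation diverged: no inliers at SD {sd:.4g}"
            )
        new_baseline = np.interp(t, t[inliers], values[inliers])
        delta = float(np.max(np.abs(new_baseline - baseline)))
        baseline = new_baseline
        sd = max(float((values - baseline).std()), np.finfo(float).tiny)
        if delta < tol:
            break
    residual = values - baseline
    return BaselineDecomposition(baseline, residual, sd, iterations, inliers)


def detect_spikes(
    decomp: BaselineDecomposition, threshold_sd: float = 3.0
) -> np.ndarray:
    """Binary spike train: residual local maxima above threshold_sd x SD.

    A bin is a spike when the residual is a strict local maximum (ties
    resolved to the earliest bin) and exceeds ``threshold_sd * decomp.sd``.
    """
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    r = decomp.residual
    out = np.zeros(len(r), dtype=np.uint8)
    if len(r) < 3:
        return out
    interior = np.arange(1, len(r) - 1)
    is_peak = (r[interior] > r[interior - 1]) & (r[interior] >= r[interior + 1])
    above = r[interior] > threshold_sd * decomp.sd
    out[interior[is_peak & above]] = 1
    return out


def preprocess_glia_trace(
    trace: RawTrace | np.ndarray, smooth_sigma_bins: float = 5.0
) -> np.ndarray:
    """Detrend (linear), Gaussian-smooth, and z-score a glial trace."""
    values = trace.values if isinstance(trace, RawTrace) else np.asarray(trace, float)
    if len(values) < 3:
        raise ValueError("need at least 3 timepoints")
    detrended = scipy.signal.detrend(values, type="linear")
    smoothed = scipy.ndimage.gaussian_filter1d(detrended, sigma=smooth_sigma_bins)
    sd = smoothed.std()
    if sd <= 1e-10 * max(1.0, float(values.std())):
        raise ValueError("glial trace has zero variance after detrending")
    z = (smoothed - smoothed.mean()) / sd
    # enforce the normalization contract exactly (guard against fp drift)
    z = (z - z.mean()) / z.std()
    return z
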