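"""ROI detection and fluorescence-trace extraction/normalization.

The ROI detector works on the time-averaged image: clip-normalize between the
20th and 30th intensity percentiles, subtract a wide Gaussian blur (sigma = 7
px) as a background estimate, binarize at 0.08, fill holes, open with a 4 x 4
square, and keep 8-connected components of at least 10 pixels.

Traces are extracted by spatially averaging ROI pixels per frame, smoothed
with a 5-frame boxcar, and normalized to ``r = 100 * (F - F0) / F0`` where
the baseline F0 is a smoothing spline through one reference point per 50 s
block (the sample closest to the block's 10th fluorescence percentile).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "FluorescenceMovie",
    "ROISet",
    "TraceMatrix",
    "detect_rois",
    "extract_traces",
    "normalize_traces",
]


@dataclass
class FluorescenceMovie:
    """Frame stack (frames, height, width) with its frame rate."""

    data: np.ndarray
    frame_rate: float = 20.0

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("movie must be a (frames, h, w) stack with >= 1 frame")
        if np.any(self.data < 0):
            raise ValueError("movie intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def image_size(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def time_average(self) -> np.ndarray:
        return self.data.mean(axis=0)


@dataclass
class ROISet:
    """Labelled ROI footprints; label image is 0 for background, 1..n for ROIs."""

    label_image: np.ndarray
    footprints: list[np.ndarray]  # (k, 2) pixel coordinates per ROI, 0-based

    def __len__(self) -> int:
        return len(self.footprints)

    def centroids(self) -> np.ndarray:
        if not self.footprints:
            return np.empty((0, 2))
        return np.array([pix.mean(axis=0) for pix in self.footprints])


def detect_rois(
    movie: FluorescenceMovie,
    blur_sigma: float = 7.0,
    threshold: float = 0.08,
    opening_size: int = 4,
    min_pixels: int = 10,
    connectivity: int = 8,
) -> ROISet:
    """Detect ROIs from the time-averaged image.

    The binarization threshold applies directly to the background-subtracted
    image (which may contain negative values).  Components are labelled with
    8-connectivity by default and ordered by centroid (row, col) so labels
    are deterministic.
    """
    img = movie.time_average().astype(np.float64)
    q20, q30 = np.quantile(img, [0.20, 0.30])
    if q30 > q20:
        norm = np.clip((img - q20) / (q30 - q20), 0.0, 1.0)
    else:  # (near-)constant image: nothing to detect
        return ROISet(np.zeros(img.shape, dtype=np.int32), [])
    blur = ndimage.gaussian_filter(norm, sigma=blur_sigma)
    enhanced = norm - blur
    binary = enhanced > threshold
    binary = ndimage.binary_fill_holes(binary)
    binary = ndimage.binary_opening(
        binary, structure=np.ones((opening_size, opening_size), dtype=bool)
    )
    structure = (
        np.ones((3, 3), dtype=bool) if connectivity == 8 else None
    )
    labels, n_raw = ndimage.label(binary, structure=structure)
    footprints = []
    for lab in range(1, n_raw + 1):
        pix = np.argwhere(labels == lab)
        if len(pix) >= min_pixels:
            footprints.append(pix)
    footprints.sort(key=lambda pix: tuple(pix.mean(axis=0)))
    label_image = np.zeros(img.shape, dtype=np.int32)
    for i, pix in enumerate(footprints, start=1):
        label_image[pix[:, 0], pix[:, 1]] = i
    return ROISet(label_image, footprints)


def extract_traces(movie: FluorescenceMovie, rois: ROISet) -> np.ndarray:
    """Raw trace matrix F (ROI x frame): spatial mean over ROI pixels."""
    if len(rois) == 0:
        return np.empty((0, movie.n_frames))
    h, w = movie.image_size
    flat = movie.data.reshape(movie.n_frames, h * w)
    traces = np.empty((len(rois), movie.n_frames), dtype=np.float64)
    for i, pix in enumerate(rois.footprints):
        if (pix[:, 0] >= h).any() or (pix[:, 1] >= w).any() or (pix < 0).any():
            raise ValueError(f"ROI {i + 1} has pixels outside the image")
        idx = pix[:, 0] * w + pix[:, 1]
        traces[i] = flat[:, idx].mean(axis=1)
    return traces


@dataclass
class TraceMatrix:
    """Raw, smoothed and normalized traces plus the fitted baseline."""

    f_raw: np.ndarray  # as extracted
    f_smooth: np.ndarray  # 5-frame boxcar
    f0: np.ndarray  # fitted baseline
    r: np.ndarray  # 100 * (F_smooth - F0) / F0, %dF/F0
    frame_rate: float
    valid: np.ndarray  # False where F0 <= 0 somewhere (trace excluded downstream)

    @property
    def n_traces(self) -> int:
        return self.f_raw.shape[0]

    @property
    def n_frames(self) -> int:
        return self.f_raw.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


def _block_edges(n_frames: int, frame_rate: float, block_s: float) -> list[tuple[int, int]]:
    """50 s blocks; a trailing partial block keeps its own reference point if
    it is at least 10 s long, otherwise it is merged into the previous one."""
    block = round(block_s * frame_rate)
    min_partial = round(10.0 * frame_rate)
    edges = list(range(0, n_frames, block))
    spans = [(a, min(a + block, n_frames)) for a in edges]
    if len(spans) > 1 and spans[-1][1] - spans[-1][0] < min_partial:
        last = spans.pop()
        spans[-1] = (spans[-1][0], last[1])
    return spans


def normalize_traces(
    f_raw: np.ndarray,
    frame_rate: float,
    block_s: float = 50.0,
    baseline_percentile: float = 10.0,
    boxcar: int = 5,
    spline_lam: float | None = 1e6,
) -> TraceMatrix:
    """Baseline-correct and normalize raw traces to %dF/F0.

    ``spline_lam`` is the smoothing-spline stiffness (roughness penalty on
    the second derivative, frame units); the default keeps the fitted
    baseline to at most one inflection per 100 s while still following slow
    drift.  Quantiles use linear interpolation throughout.
    """
    f_raw = np.atleast_2d(np.asarray(f_raw, dtype=np.float64))
    n, T = f_raw.shape
    if T < 2:
        raise ValueError("need at least 2 frames")
    # trailing (causal) boxcar: no spike energy leaks before the onset frame,
    # so event detection has a constant latency instead of an early jitter
    f_smooth = ndimage.uniform_filter1d(
        f_raw, size=boxcar, axis=1, mode="nearest", origin=(boxcar - 1) // 2
    )
    spans = _block_edges(T, frame_rate, block_s)
    ref_x = np.empty((n, len(spans)))
    ref_y = np.empty((n, len(spans)))
    for b, (a, z) in enumerate(spans):
        block_vals = f_smooth[:, a:z]
        q = np.quantile(block_vals, baseline_percentile / 100.0, axis=1)
        idx = np.argmin(np.abs(block_vals - q[:, None]), axis=1)
        ref_x[:, b] = a + idx
        ref_y[:, b] = block_vals[np.arange(n), idx]
    f0 = np.empty_like(f_smooth)
    x = np.arange(T, dtype=np.float64)
    for i in range(n):
        if len(spans) < 5 or spline_lam is None:
            # too few points for a cubic smoothing spline: linear interpolation
            f0[i] = np.interp(x, ref_x[i], ref_y[i])
        else:
            spl = make_smoothing_spline(ref_x[i], ref_y[i], lam=spline_lam)
            # hold the baseline flat outside the reference-point range:
            # spline extrapolation at the recording edges is unconstrained
            f0[i] = spl(np.clip(x, ref_x[i, 0], ref_x[i, -1]))
    valid = (f0 > 0).all(axis=1)
    r = np.zeros_like(f_smooth)
    safe = np.where(f0 > 0, f0, 1.0)
    r[valid] = (100.0 * (f_smooth - safe) / safe)[valid]
    return TraceMatrix(
        f_raw=f_raw, f_smooth=f_smooth, f0=f0, r=r, frame_rate=frame_rate, valid=valid
    )
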