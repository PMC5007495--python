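"""Single-molecule fluorescence peak detection and quantification.

Detection pipeline: conservative smoothing -> white top-hat -> robust
threshold -> region growing.  Each accepted region yields one peak at the
brightest pixel of the *original* frame, quantified as the raw 3x3-pixel sum
around that maximum.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.morphology import disk, white_tophat

from .types import Frame, Modality
from .segmentation import CellContour

__all__ = [
    "Peak",
    "SpotParams",
    "SnrSummary",
    "conservative_smooth",
    "detect_peaks",
    "peak_intensity",
    "assign_peaks",
    "estimate_snr",
]


@dataclass
class Peak:
    """One detected fluorescence peak.

    ``intensity_counts`` is the sum of the 9 original-frame pixels centred on
    the maximum; positions within 1 px of a border are never emitted because
    the 3x3 window would be undefined there.
    """

    row: int
    col: int
    intensity_counts: float
    cell_id: int | None = None
    excluded_from_features: bool = False

    def __post_init__(self) -> None:
        if self.intensity_counts < 0:
            raise ValueError("intensity_counts must be >= 0")


@dataclass
class SpotParams:
    conservative_smoothing_radius_px: int = 1
    tophat_disk_radius_px: int = 3
    threshold_k: float = 9.0
    region_grow_low_k: float = 5.0
    min_region_px: int = 2
    max_region_px: int = 50
    min_peak_separation_px: float = 3.0

    def __post_init__(self) -> None:
        if self.conservative_smoothing_radius_px < 1 or self.tophat_disk_radius_px < 1:
            raise ValueError("filter radii must be >= 1")
        if not self.threshold_k > self.region_grow_low_k >= 0:
            raise ValueError("require threshold_k > region_grow_low_k >= 0")


@dataclass
class SnrSummary:
    per_peak: np.ndarray
    mean: float
    sd: float


def conservative_smooth(img: np.ndarray, radius: int = 1) -> np.ndarray:
    """Clamp each pixel to the [min, max] range of its neighbourhood
    (centre pixel excluded)."""
    img = np.asarray(img, dtype=float)
    size = 2 * radius + 1
    footprint = np.ones((size, size), dtype=bool)
    footprint[radius, radius] = False
    hi = ndi.maximum_filter(img, footprint=footprint, mode="nearest")
    lo = ndi.minimum_filter(img, footprint=footprint, mode="nearest")
    return np.clip(img, lo, hi)


def peak_intensity(frame: Frame | np.ndarray, row: int, col: int) -> float:
    """Exact sum of the 3x3 pixel window centred at (row, col)."""
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    h, w = pixels.shape
    if not (1 <= row <= h - 2 and 1 <= col <= w - 2):
        raise ValueError(f"3x3 window at ({row}, {col}) extends beyond the frame")
    return float(pixels[row - 1 : row + 2, col - 1 : col + 2].sum(dtype=np.float64))


def detect_peaks(fluo_frame: Frame, params: SpotParams | None = None) -> list[Peak]:
    """Detect fluorescence peaks in one frame.

    Background statistics for the thresholds are robust: mean/SD of the
    top-hat image restricted to its lower three quartiles, so large labelled
    areas do not inflate the threshold.
    """
    params = params or SpotParams()
    img = np.asarray(fluo_frame.pixels, dtype=float)
    if img.ndim != 2:
        raise ValueError("fluorescence frame must be 2-D")
    if fluo_frame.modality is not Modality.FLUORESCENCE:
        raise ValueError("detect_peaks requires a fluorescence frame")
    h, w = img.shape

    smoothed = conservative_smooth(img, params.conservative_smoothing_radius_px)
    tophat = white_tophat(smoothed, footprint=disk(params.tophat_disk_radius_px))
    q75 = np.percentile(tophat, 75)
    bg = tophat[tophat <= q75]
    mu, sd = float(bg.mean()), float(bg.std())
    hi_level = mu + params.threshold_k * sd
    lo_level = mu + params.region_grow_low_k * sd

    labels, n_regions = ndi.label(tophat >= lo_level)
    if n_regions == 0:
        return []
    seed_labels = np.unique(labels[tophat >= hi_level])
    seed_labels = seed_labels[seed_labels > 0]
    if seed_labels.size == 0:
        return []
    sizes = np.bincount(labels.ravel())
    seed_labels = [
        int(lab)
        for lab in seed_labels
        if params.min_region_px <= sizes[lab] <= params.max_region_px
    ]
    if not seed_labels:
        return []
    # one candidate per local maximum of the ORIGINAL frame inside each
    # accepted region (a region may hold several nearby molecules)
    keep = np.zeros(n_regions + 1, dtype=bool)
    keep[seed_labels] = True
    region_mask = keep[labels]
    maxima = peak_local_max(
        np.where(region_mask, img, -np.inf),
        min_distance=1,
        threshold_abs=float(img.min()),
        exclude_border=False,
    )

    # the maximum itself must clear the high threshold in the top-hat image,
    # otherwise noise bumps on the flanks of bright molecules leak through
    candidates = [
        (int(r), int(c))
        for r, c in maxima
        if 1 <= r <= h - 2 and 1 <= c <= w - 2 and tophat[r, c] >= hi_level
    ]
    # merge close detections, keeping the brighter maximum
    candidates.sort(key=lambda rc: -img[rc])
    kept: list[tuple[int, int]] = []
    for r, c in candidates:
        if all(
            math.hypot(r - r0, c - c0) >= params.min_peak_separation_px
            for r0, c0 in kept
        ):
            kept.append((r, c))
    kept.sort()
    return [Peak(r, c, peak_intensity(img, r, c)) for r, c in kept]


def assign_peaks(peaks: list[Peak], contours: list[CellContour]) -> list[Peak]:
    """Assign each peak to the contour whose mask contains its maximum.

    When overlapping masks both contain a peak, the contour with the nearest
    centroid wins (deterministic).  Unassigned peaks and peaks on edge-flagged
    cells are kept but marked excluded from feature extraction.
    """
    for peak in peaks:
        owners = [c for c in contours if c.mask[peak.row, peak.col]]
        if len(owners) > 1:
            owners.sort(
                key=lambda c: math.hypot(
                    peak.row - c.centroid[0], peak.col - c.centroid[1]
                )
            )
        if owners:
            owner = owners[0]
            peak.cell_id = owner.cell_id
            peak.excluded_from_features = owner.touches_edge
        else:
            peak.cell_id = None
            peak.excluded_from_features = True
    return peaks


def estimate_snr(
    frame: Frame | np.ndarray,
    peaks: list[Peak],
    annulus_inner_px: float = 5.0,
    annulus_outer_px: float = 8.0,
) -> SnrSummary:
    """Per-peak SNR = (peak maximum - local background median) / background SD.

    Background statistics come from an annulus around each peak.  Annulus
    pixels lying close to any *other* detected peak are excluded, and the SD
    is a robust (median-absolute-deviation) estimate, so neighbouring
    molecules do not inflate the background.
    """
    if not peaks:
        raise ValueError("estimate_snr requires at least one peak")
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    pixels = pixels.astype(float)
    h, w = pixels.shape
    ext = int(math.ceil(annulus_outer_px))
    rr, cc = np.mgrid[-ext : ext + 1, -ext : ext + 1]
    d = np.hypot(rr, cc)
    ring = (d > annulus_inner_px) & (d <= annulus_outer_px)
    dr, dc = rr[ring], cc[ring]

    signal = np.zeros((h, w), dtype=bool)
    for peak in peaks:
        signal[peak.row, peak.col] = True
    signal = ndi.binary_dilation(signal, structure=disk(3))

    snrs = np.empty(len(peaks))
    for k, peak in enumerate(peaks):
        rows = peak.row + dr
        cols = peak.col + dc
        valid = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        rows, cols = rows[valid], cols[valid]
        clean = ~signal[rows, cols]
        if clean.sum() >= 10:
            rows, cols = rows[clean], cols[clean]
        vals = pixels[rows, cols]
        med = float(np.median(vals))
        sd = 1.4826 * float(np.median(np.abs(vals - med)))
        if sd == 0:
            sd = float(vals.std())
        if sd == 0:
            raise ValueError(f"zero background SD in annulus of peak at "
                             f"({peak.row}, {peak.col})")
        snrs[k] = (pixels[peak.row, peak.col] - med) / sd
    return SnrSummary(per_peak=snrs, mean=float(snrs.mean()), sd=float(snrs.std()))
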