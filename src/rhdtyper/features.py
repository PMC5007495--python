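"""Feature extraction: seven per-image features and their per-sample means.

All features are computed on non-edge cells only.  Distances are in
micrometres, areas in um^2, intensities in camera counts.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .segmentation import CellContour
from .spots import Peak
from .types import Frame

__all__ = [
    "FEATURE_NAMES",
    "EmptyImageError",
    "CellFeatureRecord",
    "ImageFeatureVector",
    "SampleFeatureVector",
    "cell_features",
    "image_features",
    "sample_features",
]

FEATURE_NAMES = (
    "number_of_peaks",
    "cell_intensity",
    "sd_cell_intensity",
    "peak_density",
    "distance_complete",
    "distance_nearest",
    "intensity_ratio",
)


class EmptyImageError(ValueError):
    """Raised when an image has no usable (non-edge) cell."""


@dataclass
class CellFeatureRecord:
    cell_id: int
    n_peaks: int
    mean_peak_intensity: float | None
    area_um2: float
    mean_pairwise_distance_um: float | None
    mean_nearest_distance_um: float | None


@dataclass
class ImageFeatureVector:
    number_of_peaks: float
    cell_intensity: float
    sd_cell_intensity: float
    peak_density: float
    distance_complete: float
    distance_nearest: float
    intensity_ratio: float
    n_cells: int
    has_signal: bool
    total_peaks: int  # auxiliary; not a classification input

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


@dataclass
class SampleFeatureVector:
    number_of_peaks: float
    cell_intensity: float
    sd_cell_intensity: float
    peak_density: float
    distance_complete: float
    distance_nearest: float
    intensity_ratio: float
    n_images: int

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


def cell_features(
    contour: CellContour, peaks: list[Peak], pixel_pitch_um: float
) -> CellFeatureRecord:
    """Per-cell statistics of the peaks assigned to one non-edge cell."""
    if contour.touches_edge:
        raise ValueError("edge-flagged cells must be filtered out upstream")
    for p in peaks:
        if p.cell_id != contour.cell_id:
            raise ValueError("peak not assigned to this cell")
    n = len(peaks)
    area_um2 = contour.area_px * pixel_pitch_um**2
    mean_intensity = (
        float(np.mean([p.intensity_counts for p in peaks])) if n >= 1 else None
    )
    mean_pairwise = mean_nearest = None
    if n >= 2:
        pts = np.array([[p.row, p.col] for p in peaks], dtype=float)
        dists = pdist(pts) * pixel_pitch_um
        mean_pairwise = float(dists.mean())
        dm = squareform(dists)
        np.fill_diagonal(dm, np.inf)
        mean_nearest = float(dm.min(axis=1).mean())
    return CellFeatureRecord(
        cell_id=contour.cell_id,
        n_peaks=n,
        mean_peak_intensity=mean_intensity,
        area_um2=area_um2,
        mean_pairwise_distance_um=mean_pairwise,
        mean_nearest_distance_um=mean_nearest,
    )


def image_features(
    contours: list[CellContour],
    peaks: list[Peak],
    fluo_frame: Frame,
    pixel_pitch_um: float,
) -> ImageFeatureVector:
    """The seven image-level features.

    Cells without peaks participate in ``number_of_peaks`` and
    ``peak_density`` but not in the intensity/distance features; features that
    are undefined on an image (no labelled cell, no cell with >= 2 peaks) are
    encoded as 0 with ``has_signal`` reporting whether any cell carried
    signal.
    """
    usable = [c for c in contours if not c.touches_edge]
    if not usable:
        raise EmptyImageError("image has no non-edge cell")
    by_cell: dict[int, list[Peak]] = {c.cell_id: [] for c in usable}
    for p in peaks:
        if p.excluded_from_features or p.cell_id is None:
            continue
        if p.cell_id in by_cell:
            by_cell[p.cell_id].append(p)

    records = [
        cell_features(c, by_cell[c.cell_id], pixel_pitch_um) for c in usable
    ]
    n_cells = len(records)
    total_peaks = sum(r.n_peaks for r in records)
    number_of_peaks = total_peaks / n_cells
    peak_density = float(np.mean([r.n_peaks / r.area_um2 for r in records]))

    with_signal = [r.mean_peak_intensity for r in records if r.n_peaks >= 1]
    has_signal = len(with_signal) > 0
    cell_intensity = float(np.mean(with_signal)) if has_signal else 0.0
    sd_cell_intensity = float(np.std(with_signal)) if has_signal else 0.0

    pairwise = [r.mean_pairwise_distance_um for r in records if r.n_peaks >= 2]
    nearest = [r.mean_nearest_distance_um for r in records if r.n_peaks >= 2]
    distance_complete = float(np.mean(pairwise)) if pairwise else 0.0
    distance_nearest = float(np.mean(nearest)) if nearest else 0.0

    pixels = np.asarray(fluo_frame.pixels, dtype=float)
    inside = np.zeros(pixels.shape, dtype=bool)
    for c in usable:
        inside |= c.mask
    any_mask = inside.copy()
    for c in contours:
        any_mask |= c.mask
    outside = ~any_mask
    mean_out = float(pixels[outside].mean()) if outside.any() else 0.0
    mean_in = float(pixels[inside].mean()) if inside.any() else 0.0
    intensity_ratio = mean_in / mean_out if mean_out > 0 else 0.0

    return ImageFeatureVector(
        number_of_peaks=number_of_peaks,
        cell_intensity=cell_intensity,
        sd_cell_intensity=sd_cell_intensity,
        peak_density=peak_density,
        distance_complete=distance_complete,
        distance_nearest=distance_nearest,
        intensity_ratio=intensity_ratio,
        n_cells=n_cells,
        has_signal=has_signal,
        total_peaks=total_peaks,
    )


def sample_features(images: list[ImageFeatureVector]) -> SampleFeatureVector:
    """Arithmetic mean of each feature over a sample's images."""
    if not images:
        raise ValueError("sample_features requires at least one image")
    means = np.mean([iv.as_array() for iv in images], axis=0)
    return SampleFeatureVector(
        **dict(zip(FEATURE_NAMES, (float(v) for v in means))),
        n_images=len(images),
    )
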