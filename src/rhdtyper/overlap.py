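"""Binned peak-intensity distributions and pairwise overlap percentages.

Histograms share a fixed origin (default 0 counts) and bin width (default 50
counts) and are normalised to relative frequencies before per-bin minima are
summed, so populations of different size are comparable.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import RhDLabel

__all__ = [
    "IntensityHistogram",
    "intensity_histogram",
    "distribution_overlap",
    "pairwise_overlap_matrix",
]


@dataclass
class IntensityHistogram:
    bin_width: float
    origin: float
    frequencies: np.ndarray  # relative frequency per half-open bin from origin
    n: int

    def bin_start(self, index: int) -> float:
        return self.origin + index * self.bin_width


def intensity_histogram(
    intensities: Sequence[float] | np.ndarray,
    bin_width: float = 50.0,
    origin: float = 0.0,
) -> IntensityHistogram:
    """Histogram over half-open bins [origin + i*w, origin + (i+1)*w),
    normalised to unit mass."""
    arr = np.asarray(intensities, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot build a histogram from no intensities")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if (arr < origin).any():
        raise ValueError("intensities below the histogram origin")
    idx = np.floor((arr - origin) / bin_width).astype(int)
    freq = np.bincount(idx).astype(float)
    return IntensityHistogram(
        bin_width=bin_width, origin=origin, frequencies=freq / arr.size, n=arr.size
    )


def distribution_overlap(h1: IntensityHistogram, h2: IntensityHistogram) -> float:
    """Overlap fraction: sum over bins of the minimum relative frequency."""
    if h1.bin_width != h2.bin_width or h1.origin != h2.origin:
        raise ValueError("histograms must share bin width and origin")
    n = max(len(h1.frequencies), len(h2.frequencies))
    f1 = np.zeros(n)
    f2 = np.zeros(n)
    f1[: len(h1.frequencies)] = h1.frequencies
    f2[: len(h2.frequencies)] = h2.frequencies
    return float(np.minimum(f1, f2).sum())


def pairwise_overlap_matrix(
    populations: Mapping[RhDLabel, Sequence[float]],
    bin_width: float = 50.0,
    origin: float = 0.0,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise overlap fractions; diagonal is 1."""
    if len(populations) < 2:
        raise ValueError("need at least two populations")
    labels = list(populations)
    hists = {
        lab: intensity_histogram(populations[lab], bin_width, origin)
        for lab in labels
    }
    names = [lab.name for lab in labels]
    mat = pd.DataFrame(np.eye(len(labels)), index=names, columns=names)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            val = distribution_overlap(hists[a], hists[b])
            mat.loc[a.name, b.name] = val
            mat.loc[b.name, a.name] = val
    return mat
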