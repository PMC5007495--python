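"""Erythrocyte detection in bright-field frames.

Pipeline: mean filter -> gradient magnitude -> convolution with an annular
("ring") kernel matched to the expected cell radius -> threshold at
mean + k*SD of the response -> local maxima as centre candidates -> circular
seed -> greedy active-contour refinement.  Incompletely imaged cells are
flagged by mask/border intersection.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import fftconvolve
from skimage.draw import polygon2mask
from skimage.feature import peak_local_max

from .types import Frame, Modality

__all__ = [
    "CellContour",
    "SegmentationParams",
    "circular_nodes",
    "edge_map",
    "evolve_snake",
    "snake_energy",
    "refine_contour",
    "detect_cells",
    "flag_edge_cells",
]


@dataclass
class CellContour:
    """Closed contour and interior mask of one detected erythrocyte."""

    cell_id: int
    nodes: np.ndarray  # (n, 2) sub-pixel (row, col); closed implicitly
    mask: np.ndarray  # boolean raster of interior pixels
    area_px: int
    centroid: tuple[float, float]
    touches_edge: bool = False
    energy: float = 0.0

    def __post_init__(self) -> None:
        if self.area_px != int(self.mask.sum()):
            raise ValueError("area_px must equal mask pixel count")


@dataclass
class SegmentationParams:
    mean_filter_radius_px: int = 2
    cell_radius_px: float = 23.0
    ring_kernel_inner_radius_px: float | None = None  # default 0.7 * cell_radius
    ring_kernel_outer_radius_px: float | None = None  # default 1.3 * cell_radius
    detection_threshold_k: float = 4.0
    seed_radius_factor: float = 1.15
    snake_nodes: int = 48
    snake_alpha: float = 0.01
    snake_beta: float = 0.05
    snake_gamma: float = 1.0
    max_iterations: int = 40
    convergence_eps_px: float = 0.2
    max_mask_overlap: float = 0.10

    def __post_init__(self) -> None:
        inner = self.inner_radius
        outer = self.outer_radius
        if not outer > inner > 0:
            raise ValueError("ring kernel radii must satisfy outer > inner > 0")
        if min(self.snake_alpha, self.snake_beta, self.snake_gamma) < 0:
            raise ValueError("snake energy weights must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")

    @property
    def inner_radius(self) -> float:
        return (
            self.ring_kernel_inner_radius_px
            if self.ring_kernel_inner_radius_px is not None
            else 0.7 * self.cell_radius_px
        )

    @property
    def outer_radius(self) -> float:
        return (
            self.ring_kernel_outer_radius_px
            if self.ring_kernel_outer_radius_px is not None
            else 1.3 * self.cell_radius_px
        )


def circular_nodes(center: tuple[float, float], radius: float, n: int) -> np.ndarray:
    """n snake nodes on a circle, (row, col) order."""
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.sin(theta), center[1] + radius * np.cos(theta)]
    )


def edge_map(
    bf_pixels: np.ndarray,
    mean_filter_radius_px: int = 2,
    border_is_edge: bool = True,
) -> np.ndarray:
    """Normalised, smoothed gradient-magnitude image used as snake image energy.

    With ``border_is_edge`` the frame boundary is treated as a maximal edge so
    that contours of border-clipped cells close along the border instead of
    drifting inward.
    """
    img = np.asarray(bf_pixels, dtype=float)
    sm = ndi.uniform_filter(img, size=2 * mean_filter_radius_px + 1)
    grad = np.hypot(ndi.sobel(sm, axis=0), ndi.sobel(sm, axis=1))
    grad = ndi.gaussian_filter(grad, sigma=1.5)
    peak = grad.max()
    gmap = grad / peak if peak > 0 else grad
    if border_is_edge:
        gmap[0, :] = gmap[-1, :] = 1.0
        gmap[:, 0] = gmap[:, -1] = 1.0
    return gmap


def snake_energy(nodes: np.ndarray, gmap: np.ndarray, params: SegmentationParams) -> float:
    """Total snake energy: elasticity + bending - image (gradient) term."""
    d = nodes - np.roll(nodes, 1, axis=0)
    cont = float((d**2).sum())
    curv = np.roll(nodes, 1, axis=0) + np.roll(nodes, -1, axis=0) - 2.0 * nodes
    bend = float((curv**2).sum())
    img = float(
        ndi.map_coordinates(gmap, nodes.T, order=1, mode="nearest").sum()
    )
    return params.snake_alpha * cont + params.snake_beta * bend - params.snake_gamma * img


_OFFSETS = np.array(
    [[dr, dc] for dr in (-1, 0, 1) for dc in (-1, 0, 1)], dtype=float
)


def evolve_snake(
    nodes: np.ndarray, gmap: np.ndarray, params: SegmentationParams
) -> tuple[np.ndarray, list[float]]:
    """Greedy energy-descent refinement of a closed snake.

    Each iteration tries (a) one uniform step of every node towards the
    centroid and (b) sequential single-node moves on a 3x3 grid, accepting a
    move only when it lowers the total energy, which makes the returned
    energy trace non-increasing.  Terminates when the largest node
    displacement in an iteration drops below ``convergence_eps_px``.
    """
    nodes = np.array(nodes, dtype=float)
    n = len(nodes)
    h, w = gmap.shape
    a, b, g = params.snake_alpha, params.snake_beta, params.snake_gamma
    energy = snake_energy(nodes, gmap, params)
    trace = [energy]

    def _gvals(pts: np.ndarray) -> np.ndarray:
        return ndi.map_coordinates(gmap, pts.T, order=1, mode="nearest")

    for _it in range(params.max_iterations):
        max_disp = 0.0
        # uniform shrink candidate: step 0.5 px towards the centroid
        centroid = nodes.mean(axis=0)
        vec = centroid - nodes
        norms = np.linalg.norm(vec, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        shrunk = nodes + 0.5 * vec / norms
        shrunk[:, 0] = np.clip(shrunk[:, 0], -1, h)
        shrunk[:, 1] = np.clip(shrunk[:, 1], -1, w)
        e_shrunk = snake_energy(shrunk, gmap, params)
        if e_shrunk < energy - 1e-12:
            nodes = shrunk
            energy = e_shrunk
            max_disp = 0.5

        for i in range(n):
            pm2 = nodes[(i - 2) % n]
            pm1 = nodes[(i - 1) % n]
            pi = nodes[i]
            pp1 = nodes[(i + 1) % n]
            pp2 = nodes[(i + 2) % n]
            cand = pi + _OFFSETS
            cand[:, 0] = np.clip(cand[:, 0], -1, h)
            cand[:, 1] = np.clip(cand[:, 1], -1, w)
            # exact delta of global energy: only terms touching node i change
            cont = ((cand - pm1) ** 2).sum(axis=1) + ((pp1 - cand) ** 2).sum(axis=1)
            curv_m = pm2 + cand - 2.0 * pm1
            curv_i = pm1 + pp1 - 2.0 * cand
            curv_p = cand + pp2 - 2.0 * pp1
            bend = (curv_m**2).sum(axis=1) + (curv_i**2).sum(axis=1) + (
                curv_p**2
            ).sum(axis=1)
            local = a * cont + b * bend - g * _gvals(cand)
            stay = 4  # offset (0, 0)
            best = int(np.argmin(local))
            if best != stay and local[best] < local[stay] - 1e-12:
                energy += float(local[best] - local[stay])
                disp = float(np.linalg.norm(cand[best] - pi))
                max_disp = max(max_disp, disp)
                nodes[i] = cand[best]
        energy = snake_energy(nodes, gmap, params)  # re-sync, avoids fp drift
        trace.append(energy)
        if max_disp < params.convergence_eps_px:
            break
    return nodes, trace


def _contour_from_nodes(
    nodes: np.ndarray, shape: tuple[int, int], cell_id: int, energy: float
) -> CellContour | None:
    mask = polygon2mask(shape, nodes)
    area = int(mask.sum())
    if area < 3:
        return None
    rows, cols = np.nonzero(mask)
    return CellContour(
        cell_id=cell_id,
        nodes=nodes,
        mask=mask,
        area_px=area,
        centroid=(float(rows.mean()), float(cols.mean())),
        energy=energy,
    )


def refine_contour(
    seed_contour: CellContour, bf_frame: Frame, params: SegmentationParams | None = None
) -> CellContour:
    """Refine a seed contour by greedy snake descent on the frame's edge map."""
    params = params or SegmentationParams()
    if seed_contour.area_px < 3:
        warnings.warn("degenerate seed contour (area < 3 px); returned unchanged")
        return seed_contour
    gmap = edge_map(bf_frame.pixels, params.mean_filter_radius_px)
    nodes, trace = evolve_snake(seed_contour.nodes, gmap, params)
    refined = _contour_from_nodes(
        nodes, bf_frame.shape, seed_contour.cell_id, trace[-1]
    )
    if refined is None:
        warnings.warn("refinement collapsed the contour; returning the seed")
        return seed_contour
    refined.touches_edge = seed_contour.touches_edge
    return refined


def _ring_kernel(inner: float, outer: float) -> np.ndarray:
    ext = int(math.ceil(outer))
    rr, cc = np.mgrid[-ext : ext + 1, -ext : ext + 1]
    d = np.hypot(rr, cc)
    k = ((d >= inner) & (d <= outer)).astype(float)
    return k / k.sum()


def detect_cells(
    bf_frame: Frame, params: SegmentationParams | None = None
) -> list[CellContour]:
    """Detect all erythrocyte contours in one bright-field frame.

    Returns non-overlapping contours with consecutive ids and edge flags set.
    """
    params = params or SegmentationParams()
    img = np.asarray(bf_frame.pixels, dtype=float)
    if img.ndim != 2:
        raise ValueError("bright-field frame must be 2-D")
    if bf_frame.modality is not Modality.BRIGHT_FIELD:
        raise ValueError("detect_cells requires a bright-field frame")

    sm = ndi.uniform_filter(img, size=2 * params.mean_filter_radius_px + 1)
    grad = np.hypot(ndi.sobel(sm, axis=0), ndi.sobel(sm, axis=1))
    kernel = _ring_kernel(params.inner_radius, params.outer_radius)
    response = fftconvolve(grad, kernel, mode="same")
    threshold = response.mean() + params.detection_threshold_k * response.std()
    centres = peak_local_max(
        response,
        min_distance=max(1, int(1.1 * params.cell_radius_px)),
        threshold_abs=threshold,
        exclude_border=False,
    )

    gmap = edge_map(img, params.mean_filter_radius_px)
    candidates: list[CellContour] = []
    for cr, cc in centres:
        seed = circular_nodes(
            (float(cr), float(cc)),
            params.seed_radius_factor * params.cell_radius_px,
            params.snake_nodes,
        )
        seed[:, 0] = np.clip(seed[:, 0], -1, img.shape[0])
        seed[:, 1] = np.clip(seed[:, 1], -1, img.shape[1])
        nodes, trace = evolve_snake(seed, gmap, params)
        contour = _contour_from_nodes(nodes, img.shape, len(candidates), trace[-1])
        if contour is not None:
            candidates.append(contour)

    # overlap resolution: keep the lower-energy contour of any pair whose
    # mask intersection exceeds the tolerance fraction of the smaller mask
    candidates.sort(key=lambda c: c.energy)
    kept: list[CellContour] = []
    for cand in candidates:
        ok = True
        for other in kept:
            inter = int((cand.mask & other.mask).sum())
            if inter > params.max_mask_overlap * min(cand.area_px, other.area_px):
                ok = False
                break
        if ok:
            kept.append(cand)
    for new_id, contour in enumerate(kept):
        contour.cell_id = new_id
    return flag_edge_cells(kept, img.shape)


def flag_edge_cells(
    contours: list[CellContour], frame_shape: tuple[int, int]
) -> list[CellContour]:
    """Set ``touches_edge`` exactly for contours whose mask meets the border."""
    h, w = frame_shape
    for contour in contours:
        m = contour.mask
        contour.touches_edge = bool(
            m[0, :].any() or m[h - 1, :].any() or m[:, 0].any() or m[:, w - 1].any()
        )
    return contours
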