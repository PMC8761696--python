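"""Gradient-orientation pixel classification of brightfield organoid images.

Each frame is smoothed, the local intensity gradient is evaluated, and every
pixel is classified by comparing its intensity against interpolated samples
taken one step forward and backward along the gradient direction:

* ``Background`` — gradient magnitude below threshold (or locally flat),
* ``Ridge`` — brighter than both neighbours (bright crest),
* ``Valley`` — darker than both neighbours (dark trough, e.g. organoid rim),
* ``Rising`` / ``Falling`` — monotone slope along the gradient direction.

Boundary-class structures that only touch background are treated as noise,
slope bands are eroded back toward the true edge, closed boundaries are
filled, and a size exclusion removes debris. The surviving components are
the per-frame organoid mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PixelClass",
    "ImageStack",
    "SegmentationConfig",
    "OrganoidMask",
    "gaussian_smooth",
    "compute_gradient",
    "classify_pixels",
    "cleanup_and_fill",
    "segment_stack",
]

_EPS = 1e-9
_CROSS = ndimage.generate_binary_structure(2, 1)  # 3x3 cross
_EIGHT = ndimage.generate_binary_structure(2, 2)  # 3x3 full


class PixelClass(IntEnum):
    BACKGROUND = 0
    RIDGE = 1
    VALLEY = 2
    RISING = 3
    FALLING = 4


@dataclass
class ImageStack:
    """Time-lapse grayscale frames with acquisition times in minutes."""

    frames: np.ndarray  # (n_frames, H, W) float in [0, 1]
    timestamps: np.ndarray  # minutes

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be (n_frames, H, W) with >= 1 frame")
        if len(self.timestamps) != self.frames.shape[0]:
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class SegmentationConfig:
    """Tunable parameters of the pixel-classification pipeline.

    ``background_magnitude_threshold`` may be a float in gradient units or
    ``"auto"`` (Otsu on the gradient-magnitude histogram).
    """

    sigma: float = 1.3
    background_magnitude_threshold: float | str = "auto"
    neighbor_step: float = 1.0
    erosion_iterations: int = 1
    min_area: float = 500.0
    fill_holes: bool = True
    gradient_operator: str = "central"  # or "sobel"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")
        if self.gradient_operator not in ("central", "sobel"):
            raise ValueError("gradient_operator must be 'central' or 'sobel'")


@dataclass
class OrganoidMask:
    """Binary organoid mask for one frame plus its connected components."""

    mask: np.ndarray  # bool (H, W)
    components: pd.DataFrame  # columns: component_id, area_px2

    @property
    def total_area(self) -> float:
        return float(self.components["area_px2"].sum())

    @property
    def labels(self) -> np.ndarray:
        lab, _ = ndimage.label(self.mask, structure=_EIGHT)
        return lab


def gaussian_smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blur with reflective boundary handling."""
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return ndimage.gaussian_filter(image, sigma=sigma, mode="reflect")


def compute_gradient(
    image: np.ndarray, operator: str = "central"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel gradient magnitude and direction.

    Direction is atan2(d/drow, d/dcol) in (-pi, pi]; pixels with zero
    magnitude get direction 0 by convention.
    """
    image = np.asarray(image, dtype=float)
    if image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    if operator == "central":
        gr, gc = np.gradient(image)
    elif operator == "sobel":
        gr = ndimage.sobel(image, axis=0) / 8.0
        gc = ndimage.sobel(image, axis=1) / 8.0
    else:
        raise ValueError(f"unknown gradient operator {operator!r}")
    magnitude = np.hypot(gr, gc)
    direction = np.arctan2(gr, gc)
    direction[magnitude == 0] = 0.0
    return magnitude, direction


def _resolve_threshold(magnitude: np.ndarray, threshold) -> float:
    if threshold != "auto":
        return float(threshold)
    if magnitude.max() - magnitude.min() < _EPS:
        return np.inf  # flat image: everything is background
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(magnitude))


def classify_pixels(
    smoothed: np.ndarray,
    magnitude: np.ndarray,
    direction: np.ndarray,
    config: SegmentationConfig,
) -> np.ndarray:
    """Label every pixel with one of the five classes (total partition).

    Intensity is sampled at +/- ``neighbor_step`` along the local gradient
    direction with bilinear interpolation. Ties (differences within 1e-9)
    break toward Rising/Falling by the sign of the one strict difference;
    fully flat pixels are Background.
    """
    if not (smoothed.shape == magnitude.shape == direction.shape):
        raise ValueError("inputs must share one shape")
    thr = _resolve_threshold(magnitude, config.background_magnitude_threshold)

    # sample along the gradient *orientation* (mod pi): the gradient vector
    # itself always points uphill, which would make every slope "Rising"
    orientation = np.mod(direction + np.pi / 2, np.pi) - np.pi / 2
    rows, cols = np.indices(smoothed.shape, dtype=float)
    dr = np.sin(orientation) * config.neighbor_step
    dc = np.cos(orientation) * config.neighbor_step
    fwd = ndimage.map_coordinates(
        smoothed, [rows + dr, cols + dc], order=1, mode="nearest"
    )
    bwd = ndimage.map_coordinates(
        smoothed, [rows - dr, cols - dc], order=1, mode="nearest"
    )

    df = fwd - smoothed  # forward minus center
    db = bwd - smoothed  # backward minus center
    sf = np.where(np.abs(df) <= _EPS, 0, np.sign(df)).astype(int)
    sb = np.where(np.abs(db) <= _EPS, 0, np.sign(db)).astype(int)

    out = np.full(smoothed.shape, PixelClass.BACKGROUND, dtype=np.uint8)
    sig = magnitude >= thr
    ridge = sig & (sf < 0) & (sb < 0)
    valley = sig & (sf > 0) & (sb > 0)
    rising = sig & (((sf > 0) & (sb <= 0)) | ((sf == 0) & (sb < 0)))
    falling = sig & (((sf < 0) & (sb >= 0)) | ((sf == 0) & (sb > 0)))
    # ridge/valley take precedence over the tie-broken slope classes
    rising &= ~(ridge | valley)
    falling &= ~(ridge | valley | rising)
    out[rising] = PixelClass.RISING
    out[falling] = PixelClass.FALLING
    out[ridge] = PixelClass.RIDGE
    out[valley] = PixelClass.VALLEY
    return out


def _drop_background_only_boundaries(classmap: np.ndarray) -> np.ndarray:
    """Remove open Ridge/Valley fragments surrounded entirely by Background.

    A component survives if it touches any non-Background pixel or if it is a
    closed curve (it encloses interior pixels): closed boundaries delimit
    objects even when their surroundings are flat.
    """
    boundary = (classmap == PixelClass.RIDGE) | (classmap == PixelClass.VALLEY)
    nonbg = classmap != PixelClass.BACKGROUND
    lab, n = ndimage.label(boundary, structure=_EIGHT)
    keep = np.zeros(n + 1, dtype=bool)
    for i, sl in enumerate(ndimage.find_objects(lab), start=1):
        if sl is None:
            continue
        sl = tuple(
            slice(max(s.start - 1, 0), s.stop + 1) for s in sl
        )
        comp = lab[sl] == i
        ring = ndimage.binary_dilation(comp, structure=_EIGHT) & ~comp
        touches_structure = bool(np.any(nonbg[sl] & ring))
        encloses = bool(ndimage.binary_fill_holes(comp).sum() > comp.sum())
        keep[i] = touches_structure or encloses
    return keep[lab]


def cleanup_and_fill(classmap: np.ndarray, config: SegmentationConfig) -> OrganoidMask:
    """Turn a pixel class map into a binary organoid mask.

    Steps: (1) drop Ridge/Valley components adjacent only to Background;
    (2) erode Rising/Falling bands; (3) fill holes enclosed by the remaining
    boundary pixels; (4) remove components smaller than ``min_area``.
    """
    classmap = np.asarray(classmap)
    boundary = _drop_background_only_boundaries(classmap)
    bands = (classmap == PixelClass.RISING) | (classmap == PixelClass.FALLING)
    if config.erosion_iterations > 0:
        bands = ndimage.binary_erosion(
            bands, structure=_CROSS, iterations=config.erosion_iterations
        )
    candidate = boundary | bands
    if config.fill_holes:
        candidate = ndimage.binary_fill_holes(candidate)
    lab, n = ndimage.label(candidate, structure=_EIGHT)
    areas = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    rows = []
    mask = np.zeros_like(candidate, dtype=bool)
    next_id = 1
    for i in range(1, n + 1):
        if areas[i - 1] >= config.min_area:
            mask |= lab == i
            rows.append({"component_id": next_id, "area_px2": float(areas[i - 1])})
            next_id += 1
    table = pd.DataFrame(rows, columns=["component_id", "area_px2"])
    return OrganoidMask(mask=mask, components=table)


def segment_frame(image: np.ndarray, config: SegmentationConfig) -> OrganoidMask:
    """Run the full smooth -> gradient -> classify -> cleanup pipeline."""
    smoothed = gaussian_smooth(image, config.sigma)
    magnitude, direction = compute_gradient(smoothed, config.gradient_operator)
    classmap = classify_pixels(smoothed, magnitude, direction, config)
    return cleanup_and_fill(classmap, config)


def segment_stack(
    stack: ImageStack, config: SegmentationConfig | None = None
) -> tuple[list[OrganoidMask], np.ndarray]:
    """Segment every frame; returns per-frame masks and total areas (px^2)."""
    config = config or SegmentationConfig()
    masks: list[OrganoidMask] = []
    for f in range(stack.n_frames):
        try:
            masks.append(segment_frame(stack.frames[f], config))
        except Exception as exc:  # annotate failures with the frame index
            raise RuntimeError(f"segmentation failed at frame {f}: {exc}") from exc
    areas = np.array([m.total_area for m in masks])
    return masks, areas
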