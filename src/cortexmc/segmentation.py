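"""Morphological segmentation of an exposed-cortex RGB image.

The image is partitioned into large blood vessels, small blood vessels and
grey matter inside a (manually drawn) surgical-window mask:

1. RGB -> grayscale (luma weights 0.299 R + 0.587 G + 0.114 B);
2. Gaussian adaptive threshold with a 5-mm block (converted to an odd pixel
   count from the image resolution); vessels are darker than their local
   neighbourhood.  Saturated specular pixels are excluded by a plain
   grayscale threshold;
3. morphological opening with a 0.5-mm disk removes thin structures, a
   closing then yields the large-vessel mask;
4. the small-vessel mask is the thresholded image minus the large vessels;
5. grey matter is the remainder of the window.

Within the window and outside the excluded (specular) pixels the three
masks are pairwise disjoint and cover every pixel.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_local
from skimage.morphology import closing, disk, opening

__all__ = [
    "SegmentationParams",
    "TissueMasks",
    "mm_to_odd_pixels",
    "rgb_to_gray",
    "segment_cortex",
    "masks_to_labels",
    "labels_to_masks",
]

#: label values used in exported label images
LABEL_GREY = 0
LABEL_SMALL = 1
LABEL_LARGE = 2
LABEL_EXCLUDED = 255


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable segmentation parameters.

    ``block_mm``: adaptive-threshold block size (5 mm is tuned to human
    cortical vessel calibre); ``open_mm``: opening-disk diameter separating
    large from small vessels; ``offset``: grey-level offset below the local
    Gaussian mean that marks a vessel pixel; ``specular_threshold``:
    grayscale level at and above which a pixel is treated as specular
    reflection and excluded.
    """

    block_mm: float = 5.0
    open_mm: float = 0.5
    offset: float = 2.0
    specular_threshold: float = 250.0


@dataclass
class TissueMasks:
    """Binary partition of the surgical window into tissue classes."""

    large: np.ndarray
    small: np.ndarray
    grey: np.ndarray
    excluded: np.ndarray
    window: np.ndarray
    resolution_mm: float

    def check_partition(self) -> None:
        inside = self.window & ~self.excluded
        union = self.large | self.small | self.grey
        if not np.array_equal(union & inside, inside):
            raise AssertionError("masks do not cover the window")
        overlap = (self.large.astype(int) + self.small.astype(int)
                   + self.grey.astype(int))
        if np.any(overlap > 1):
            raise AssertionError("masks overlap")


def mm_to_odd_pixels(size_mm: float, resolution_mm_per_px: float) -> int:
    """Convert a physical size to an odd pixel count (ceil, then bump)."""
    if size_mm <= 0 or resolution_mm_per_px <= 0:
        raise ValueError("size and resolution must be positive")
    p = math.ceil(size_mm / resolution_mm_per_px)
    return p if p % 2 == 1 else p + 1


def rgb_to_gray(image: np.ndarray) -> np.ndarray:
    """Luma grayscale conversion of an 8-bit RGB image (float output)."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img
    return img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114


def _disk_from_diameter_mm(diameter_mm: float, resolution_mm: float) -> np.ndarray:
    d_px = mm_to_odd_pixels(diameter_mm, resolution_mm)
    return disk(d_px // 2)


def segment_cortex(image: np.ndarray,
                   resolution_mm: float,
                   window: np.ndarray | None = None,
                   params: SegmentationParams = SegmentationParams(),
                   ) -> TissueMasks:
    """Segment an exposed-cortex image into the three tissue classes."""
    gray = rgb_to_gray(image)
    if window is None:
        window = np.ones(gray.shape, dtype=bool)
    else:
        window = np.asarray(window).astype(bool)
        if window.shape != gray.shape:
            raise ValueError("window mask shape does not match the image")
    if not window.any():
        raise ValueError("empty surgical window")

    block = mm_to_odd_pixels(params.block_mm, resolution_mm)
    if block < 3:
        raise ValueError(f"adaptive-threshold block of {block} px is too small")

    # Gaussian-weighted local mean; vessels are darker than their surround.
    local_mean = threshold_local(gray, block_size=block, method="gaussian",
                                 offset=params.offset)
    thresholded = (gray < local_mean) & window

    excluded = (gray >= params.specular_threshold) & window
    thresholded &= ~excluded

    selem = _disk_from_diameter_mm(params.open_mm, resolution_mm)
    large = closing(opening(thresholded, selem), selem).astype(bool)
    large &= window & ~excluded
    # xor with the thresholded image; closing may add pixels outside the
    # thresholded set, which stay with the large-vessel class to keep the
    # three masks disjoint
    small = (thresholded ^ large) & ~large
    grey = window & ~excluded & ~large & ~small

    masks = TissueMasks(large=large, small=small, grey=grey,
                        excluded=excluded, window=window,
                        resolution_mm=resolution_mm)
    masks.check_partition()
    return masks


def masks_to_labels(masks: TissueMasks) -> np.ndarray:
    """Encode the partition into a single uint8 label image."""
    labels = np.full(masks.grey.shape, LABEL_GREY, dtype=np.uint8)
    labels[masks.small] = LABEL_SMALL
    labels[masks.large] = LABEL_LARGE
    labels[masks.excluded | ~masks.window] = LABEL_EXCLUDED
    return labels


def labels_to_masks(labels: np.ndarray, resolution_mm: float) -> TissueMasks:
    """Inverse of :func:`masks_to_labels` (window = non-excluded pixels)."""
    labels = np.asarray(labels)
    known = {LABEL_GREY, LABEL_SMALL, LABEL_LARGE, LABEL_EXCLUDED}
    present = set(np.unique(labels).tolist())
    if not present <= known:
        raise ValueError(f"unknown label values {sorted(present - known)}")
    window = labels != LABEL_EXCLUDED
    return TissueMasks(
        large=labels == LABEL_LARGE,
        small=labels == LABEL_SMALL,
        grey=labels == LABEL_GREY,
        excluded=np.zeros_like(window),
        window=window,
        resolution_mm=resolution_mm,
    )
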