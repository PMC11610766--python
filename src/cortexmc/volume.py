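"""3D labeled voxel volume built from the 2D segmentation masks.

The surface masks are padded laterally with grey matter (so no vessel label
touches a boundary voxel), replicated along depth, and the vessel
cross-sections are carved by a morphological erosion whose disk radius
grows with depth.  A vessel of surface width ``w`` therefore tapers and
vanishes at a depth proportional to ``w`` - a hemicylinder-like geometry in
which vessel thickness follows vessel diameter.  Vessels not visible at the
surface are not modeled.

Axis convention: arrays are indexed ``(row, col, z)`` with ``z = 0`` at the
illuminated top surface and isotropic voxel pitch (default 0.073 mm).
Label semantics match the transport engine's region indices:
0 = grey matter, 1 = large vessel, 2 = small vessel.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.morphology import disk, erosion

from .segmentation import TissueMasks

__all__ = ["LabelVolume", "build_volume", "write_volume", "read_volume"]

GREY = 0
LARGE_VESSEL = 1
SMALL_VESSEL = 2

DEFAULT_CLASS_NAMES = ("grey_matter", "large_vessel", "small_vessel")


@dataclass
class LabelVolume:
    """Labeled voxel grid with isotropic pitch.

    ``labels[r, c, z]`` holds the region index into ``class_names``;
    ``z = 0`` is the illuminated top surface.
    """

    labels: np.ndarray
    pitch_mm: float
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES

    def __post_init__(self):
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if self.pitch_mm <= 0:
            raise ValueError("pitch must be positive")
        if int(self.labels.max(initial=0)) >= len(self.class_names):
            raise ValueError("label value without a class name")

    @property
    def n_regions(self) -> int:
        return len(self.class_names)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(s * self.pitch_mm for s in self.labels.shape)


def build_volume(masks: TissueMasks,
                 depth_mm: float = 20.0,
                 pad_px: int | None = None,
                 taper: float = 1.0) -> LabelVolume:
    """Extrude the segmentation masks into a depth-carved label volume.

    ``taper`` is the number of depth slices per pixel of erosion radius:
    at slice z the vessel cross-section is the surface mask eroded by a
    digital disk of radius ``round(z / taper)``.  With the default of one
    slice per pixel a vessel of surface width ``w`` px disappears at depth
    ``~w/2`` px, i.e. its depth equals its radius.
    """
    pitch = masks.resolution_mm
    nz = int(round(depth_mm / pitch))
    if nz < 1:
        raise ValueError("depth smaller than one voxel")
    if taper <= 0:
        raise ValueError("taper must be positive")

    large = np.asarray(masks.large, dtype=bool)
    small = np.asarray(masks.small, dtype=bool)
    if pad_px is None:
        pad_px = max(1, int(round(0.1 * max(large.shape))))
    large = np.pad(large, pad_px, constant_values=False)
    small = np.pad(small, pad_px, constant_values=False)

    labels = np.zeros(large.shape + (nz,), dtype=np.uint8)
    prev_radius = -1
    lg, sm = large, small
    for z in range(nz):
        radius = int(round(z / taper))
        if radius != prev_radius:
            if radius > 0:
                selem = disk(radius)
                lg = erosion(large, selem)
                sm = erosion(small, selem)
            prev_radius = radius
        if not (lg.any() or sm.any()):
            break
        labels[lg, z] = LARGE_VESSEL
        labels[sm, z] = SMALL_VESSEL
    return LabelVolume(labels=labels, pitch_mm=pitch)


def write_volume(vol: LabelVolume, path: str | Path) -> None:
    """Write raw uint8 voxels + JSON header (``path`` and ``path.json``)."""
    path = Path(path)
    vol.labels.tofile(path)
    header = {
        "shape": list(vol.labels.shape),
        "pitch_mm": vol.pitch_mm,
        "dtype": "uint8",
        "order": "C",
        "axes": "row,col,z",
        "class_names": list(vol.class_names),
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(header, fh, indent=2)


def read_volume(path: str | Path) -> LabelVolume:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        header = json.load(fh)
    if header.get("dtype") != "uint8" or header.get("order") != "C":
        raise ValueError("unsupported volume encoding")
    shape = tuple(header["shape"])
    data = np.fromfile(path, dtype=np.uint8)
    if data.size != int(np.prod(shape)):
        raise ValueError("voxel payload does not match the header shape")
    labels = data.reshape(shape)
    class_names = tuple(header["class_names"])
    if int(labels.max(initial=0)) >= len(class_names):
        raise ValueError("label value without a class name")
    return LabelVolume(labels=labels, pitch_mm=float(header["pitch_mm"]),
                       class_names=class_names)
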