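"""Procedural synthetic inputs with exact ground truth.

No clinical image ships with the package; every pipeline stage is exercised
on procedurally generated stand-ins:

* :func:`generate_cortex_image` renders a pinkish grey-matter background
  crossed by dark curvilinear vessels of prescribed widths (straddling the
  0.5-mm opening threshold so both vessel classes occur) and optional
  saturated specular spots, and returns the exact masks used to draw it;
* :func:`grey_slab` and :func:`build_activation_fixture` build homogeneous
  and two-region grey-matter label volumes; the activated block is its own
  region so its partial path lengths are tracked separately, and the
  activation carries the default ground-truth concentration step
  (+5 uM HbO2, -3.75 uM Hb, +0.5 uM oxidized cytochromes, mirrored).

Vessel darkening is stylized (dark red on pink), not spectro-radiometric:
the segmentation stage uses only grayscale structure.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quantify import ActivationModel
from .segmentation import TissueMasks
from .volume import LabelVolume

__all__ = [
    "CortexFixtureSpec",
    "generate_cortex_image",
    "grey_slab",
    "build_activation_fixture",
]


@dataclass(frozen=True)
class CortexFixtureSpec:
    """Parameters of the procedural cortex image."""

    shape: tuple[int, int] = (256, 256)          # (rows, cols) px
    resolution_mm: float = 0.073
    vessel_widths_mm: tuple[float, ...] = (2.0, 0.2)
    n_specular: int = 0
    seed: int = 0
    background_rgb: tuple[int, int, int] = (205, 150, 150)
    vessel_rgb: tuple[int, int, int] = (95, 35, 35)
    noise_level: float = 0.5                     # grey levels (rms)


def _vessel_path(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Dense points of a gently curved quadratic Bezier across the image."""
    rows, cols = shape
    horizontal = rng.random() < 0.5
    if horizontal:
        p0 = np.array([rng.uniform(0.15, 0.85) * rows, 0.0])
        p2 = np.array([rng.uniform(0.15, 0.85) * rows, cols - 1.0])
    else:
        p0 = np.array([0.0, rng.uniform(0.15, 0.85) * cols])
        p2 = np.array([rows - 1.0, rng.uniform(0.15, 0.85) * cols])
    mid = 0.5 * (p0 + p2)
    p1 = mid + rng.uniform(-0.15, 0.15, size=2) * np.array([rows, cols])
    t = np.linspace(0.0, 1.0, 4 * max(rows, cols))[:, None]
    return ((1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2)


def _stamp(mask: np.ndarray, points: np.ndarray, radius_px: float) -> None:
    rows, cols = mask.shape
    r = max(int(np.ceil(radius_px)), 0)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    footprint = (yy ** 2 + xx ** 2) <= radius_px ** 2
    if not footprint.any():
        footprint[r, r] = True
    fy, fx = np.nonzero(footprint)
    fy -= r
    fx -= r
    pts = np.unique(np.round(points).astype(int), axis=0)
    for py, px in pts:
        y = py + fy
        x = px + fx
        ok = (y >= 0) & (y < rows) & (x >= 0) & (x < cols)
        mask[y[ok], x[ok]] = True


def generate_cortex_image(spec: CortexFixtureSpec = CortexFixtureSpec()):
    """Render the synthetic cortex image.

    Returns ``(image, masks)``: an 8-bit RGB array and the ground-truth
    :class:`~cortexmc.segmentation.TissueMasks` partition used to draw it
    (vessels of width >= 0.5 mm are ground-truth large vessels).
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    large = np.zeros(spec.shape, dtype=bool)
    small = np.zeros(spec.shape, dtype=bool)
    for width_mm in spec.vessel_widths_mm:
        radius_px = 0.5 * width_mm / spec.resolution_mm
        target = large if width_mm >= 0.5 else small
        pts = _vessel_path(rng, spec.shape)
        _stamp(target, pts, radius_px)
    small &= ~large
    if large.sum() + small.sum() > 0.5 * large.size:
        raise ValueError("vessels overfill the image")

    image = np.empty((rows, cols, 3), dtype=float)
    image[...] = np.asarray(spec.background_rgb, dtype=float)
    image[large | small] = np.asarray(spec.vessel_rgb, dtype=float)
    if spec.noise_level > 0:
        # spatially correlated low-amplitude texture (camera images are not
        # iid at the pixel level)
        from scipy.ndimage import gaussian_filter
        noise = gaussian_filter(rng.standard_normal(image.shape),
                                sigma=(1.5, 1.5, 0))
        image += noise * (spec.noise_level / noise.std())

    excluded = np.zeros(spec.shape, dtype=bool)
    for _ in range(spec.n_specular):
        cy = rng.integers(5, rows - 5)
        cx = rng.integers(5, cols - 5)
        spot = np.zeros(spec.shape, dtype=bool)
        _stamp(spot, np.array([[cy, cx]]), 3.0)
        image[spot] = 255.0
        excluded |= spot
    image = np.clip(image, 0, 255).astype(np.uint8)

    window = np.ones(spec.shape, dtype=bool)
    large &= ~excluded
    small &= ~excluded
    grey = window & ~excluded & ~large & ~small
    masks = TissueMasks(large=large, small=small, grey=grey,
                        excluded=excluded, window=window,
                        resolution_mm=spec.resolution_mm)
    masks.check_partition()
    return image, masks


def grey_slab(shape: tuple[int, int, int] = (32, 32, 32),
              pitch_mm: float = 0.25) -> LabelVolume:
    """Homogeneous grey-matter slab."""
    return LabelVolume(labels=np.zeros(shape, dtype=np.uint8),
                       pitch_mm=pitch_mm, class_names=("grey_matter",))


def build_activation_fixture(shape: tuple[int, int, int] = (48, 48, 40),
                             activated_fraction: float = 0.5,
                             pitch_mm: float = 0.25,
                             dc_uM: dict[str, float] | None = None,
                             ) -> tuple[LabelVolume, ActivationModel]:
    """Two-region grey-matter slab with a centrally activated block.

    ``activated_fraction`` of the lateral extent (a centred stripe through
    the full depth) is labeled ``activated_grey``, a separate region whose
    partial path lengths the transport engine tracks, so its absorption can
    be perturbed independently.  ``activated_fraction = 1`` activates the
    whole slab (the partial-volume-free limit).
    """
    if not 0.0 < activated_fraction <= 1.0:
        raise ValueError("activated fraction must be in (0, 1]")
    labels = np.zeros(shape, dtype=np.uint8)
    rows = shape[0]
    half = 0.5 * activated_fraction * rows
    lo = int(round(rows / 2 - half))
    hi = int(round(rows / 2 + half))
    if activated_fraction == 1.0:
        lo, hi = 0, rows
    labels[lo:hi, :, :] = 1
    vol = LabelVolume(labels=labels, pitch_mm=pitch_mm,
                      class_names=("grey_matter", "activated_grey"))
    act = ActivationModel(dc_uM=dc_uM) if dc_uM is not None else ActivationModel()
    return vol, act


def activated_surface_mask(vol: LabelVolume, margin_mm: float = 0.0) -> np.ndarray:
    """Top-surface mask of the activated region, optionally eroded laterally.

    Used to pool reflectance spectra away from the partial-volume edge.
    """
    surf = vol.labels[:, :, 0] == 1
    if margin_mm > 0:
        m = int(round(margin_mm / vol.pitch_mm))
        if m > 0:
            rows = np.nonzero(surf.any(axis=1))[0]
            if rows.size > 2 * m:
                keep = np.zeros_like(surf)
                keep[rows[m]:rows[-m] + 1, :] = True
                surf &= keep
    return surf
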