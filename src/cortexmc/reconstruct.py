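"""Hyperspectral image reconstruction from detected-photon records.

Absorption is applied a posteriori: each detected photon carries the weight

    w_j = prod_i exp(-mu_a,i * ppl_i,j)

over the labeled tissue regions (microscopic Beer-Lambert law).  Per pixel,

    phi = sum_j w_j / (N_launched * A_p)      [mm^-2 per launched photon]
    L   = sum_j (sum_i ppl_i,j) w_j / sum_j w_j   [mm]

are the diffuse reflectance and the weighted mean path length.  Photons can
be mapped to the pixel grid directly at the tissue surface or through a
paraxial thin-lens system described by the ray-transfer matrix

    S = T_s L_f0 T_d0,

applied independently to (x, theta_x) and (y, theta_y); at the imaging
condition 1/d0 + 1/s = 1/f0 the angle coefficient vanishes and the mapping
is a pure (negative) magnification -s/d0.  Images can be spatially binned,
non-local-means filtered, and spectrally interpolated to a 1-nm grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
from skimage.restoration import denoise_nl_means, estimate_sigma

from .spectra import ExtinctionLibrary, TissueComposition, absorption_coefficient
from .transport import PhotonBatch

__all__ = [
    "SensorGeometry",
    "SpectralCube",
    "photon_weight",
    "project_through_lens",
    "reflectance_image",
    "mean_pathlength_image",
    "build_cube",
    "spatial_binning",
    "denoise_nlm",
    "interpolate_cube",
    "pooled_spectra",
]


@dataclass(frozen=True)
class SensorGeometry:
    """Pixel grid the photons are accumulated on.

    ``mode='surface'`` bins photons at their exit position on the tissue;
    ``mode='lens'`` first maps (position, angle) through the paraxial lens
    system (``f0``, ``d0``, ``s`` in mm).  ``origin_mm`` is the physical
    coordinate of the corner of pixel (0, 0) on the chosen plane.
    """

    shape: tuple[int, int]          # (ny, nx) pixels
    pitch_mm: float
    mode: str = "surface"
    f0: float | None = None
    d0: float | None = None
    s: float | None = None
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.pitch_mm <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.mode not in ("surface", "lens"):
            raise ValueError("mode must be 'surface' or 'lens'")
        if self.mode == "lens":
            for name in ("f0", "d0", "s"):
                v = getattr(self, name)
                if v is None or v <= 0:
                    raise ValueError(f"lens mode requires {name} > 0")

    @property
    def pixel_area_mm2(self) -> float:
        return self.pitch_mm ** 2

    def system_matrix(self) -> np.ndarray:
        """2x2 ray-transfer matrix S = T_s L_f0 T_d0."""
        t_d0 = np.array([[1.0, self.d0], [0.0, 1.0]])
        lens = np.array([[1.0, 0.0], [-1.0 / self.f0, 1.0]])
        t_s = np.array([[1.0, self.s], [0.0, 1.0]])
        return t_s @ lens @ t_d0


def photon_weight(ppl: np.ndarray, mua_by_region: Sequence[float]) -> np.ndarray:
    """Microscopic Beer-Lambert weight(s) of detected photons.

    ``ppl`` is (n_regions,) or (n_photons, n_regions); the result is in
    (0, 1] per photon.
    """
    mua = np.asarray(mua_by_region, dtype=float)
    if np.any(mua < 0):
        raise ValueError("absorption coefficients must be >= 0")
    p = np.atleast_2d(np.asarray(ppl, dtype=float))
    if p.shape[1] != mua.shape[0]:
        raise ValueError("need one absorption coefficient per region")
    w = np.exp(-(p @ mua))
    return w[0] if np.asarray(ppl).ndim == 1 else w


def project_through_lens(x, y, theta_x, theta_y, geom: SensorGeometry):
    """Map exit (position, paraxial angle) pairs onto the sensor plane."""
    S = geom.system_matrix()
    xs = S[0, 0] * np.asarray(x) + S[0, 1] * np.asarray(theta_x)
    ys = S[0, 0] * np.asarray(y) + S[0, 1] * np.asarray(theta_y)
    return xs, ys


def _pixel_indices(batch: PhotonBatch, geom: SensorGeometry):
    if geom.mode == "lens":
        xs, ys = project_through_lens(batch.exit_x, batch.exit_y,
                                      batch.theta_x, batch.theta_y, geom)
    else:
        xs, ys = batch.exit_x, batch.exit_y
    ny, nx = geom.shape
    # exit_x runs along the volume's first (row) axis, exit_y along the
    # second, so image[r, c] sits above labels[r, c, 0]
    row = np.floor((xs - geom.origin_mm[0]) / geom.pitch_mm).astype(np.int64)
    col = np.floor((ys - geom.origin_mm[1]) / geom.pitch_mm).astype(np.int64)
    ok = (col >= 0) & (col < nx) & (row >= 0) & (row < ny)
    return row, col, ok


def _accumulate(batch: PhotonBatch, mua_by_region, geom: SensorGeometry):
    if geom.pixel_area_mm2 <= 0:
        raise ValueError("zero pixel area")
    w = np.atleast_1d(photon_weight(batch.ppl, mua_by_region))
    row, col, ok = _pixel_indices(batch, geom)
    flat = row[ok] * geom.shape[1] + col[ok]
    wsum = np.bincount(flat, weights=w[ok],
                       minlength=geom.shape[0] * geom.shape[1])
    pwsum = np.bincount(flat, weights=w[ok] * batch.total_path[ok],
                        minlength=geom.shape[0] * geom.shape[1])
    n_dropped = int((~ok).sum())
    return (wsum.reshape(geom.shape), pwsum.reshape(geom.shape), n_dropped)


def reflectance_image(batch: PhotonBatch, mua_by_region,
                      geom: SensorGeometry) -> np.ndarray:
    """Diffuse-reflectance image phi (per launched photon per mm^2)."""
    wsum, _, _ = _accumulate(batch, mua_by_region, geom)
    return wsum / (batch.n_launched * geom.pixel_area_mm2)


def mean_pathlength_image(batch: PhotonBatch, mua_by_region,
                          geom: SensorGeometry):
    """Weight-averaged total path length per pixel + validity mask.

    Pixels that received no photon carry L = 0 and ``valid = False``.
    """
    wsum, pwsum, _ = _accumulate(batch, mua_by_region, geom)
    valid = wsum > 0
    L = np.zeros_like(wsum)
    L[valid] = pwsum[valid] / wsum[valid]
    return L, valid


@dataclass
class SpectralCube:
    """Per-pixel, per-wavelength diffuse reflectance and mean path length."""

    phi: np.ndarray                 # (ny, nx, n_lambda)
    pathlength: np.ndarray          # (ny, nx, n_lambda), mm
    valid: np.ndarray               # (ny, nx, n_lambda) bool
    wavelengths: np.ndarray
    pitch_mm: float
    bin_factor: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.phi < 0) or np.any(self.pathlength < 0):
            raise ValueError("phi and pathlength must be non-negative")

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("phi", data=self.phi)
            fh.create_dataset("pathlength", data=self.pathlength)
            fh.create_dataset("valid", data=self.valid.astype(np.uint8))
            fh.create_dataset("wavelengths", data=self.wavelengths)
            fh.attrs["pitch_mm"] = self.pitch_mm
            fh.attrs["bin_factor"] = self.bin_factor

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "SpectralCube":
        with h5py.File(path, "r") as fh:
            return cls(
                phi=fh["phi"][...],
                pathlength=fh["pathlength"][...],
                valid=fh["valid"][...].astype(bool),
                wavelengths=fh["wavelengths"][...],
                pitch_mm=float(fh.attrs["pitch_mm"]),
                bin_factor=int(fh.attrs["bin_factor"]),
            )


def region_mua(compositions: Mapping[str, TissueComposition],
               region_names: Sequence[str],
               lib: ExtinctionLibrary, wavelength: float) -> np.ndarray:
    """Absorption coefficient per labeled region at one wavelength."""
    return np.array([
        absorption_coefficient(compositions[name], lib, wavelength)
        for name in region_names])


def build_cube(batches: Mapping[float, PhotonBatch],
               compositions: Mapping[str, TissueComposition],
               lib: ExtinctionLibrary,
               geom: SensorGeometry) -> SpectralCube:
    """Reweight photon records into a reflectance / path-length cube."""
    lams = np.array(sorted(batches))
    ny, nx = geom.shape
    phi = np.zeros((ny, nx, lams.size))
    L = np.zeros_like(phi)
    valid = np.zeros(phi.shape, dtype=bool)
    for k, lam in enumerate(lams):
        b = batches[lam]
        mua = region_mua(compositions, b.region_names, lib, lam)
        phi[:, :, k] = reflectance_image(b, mua, geom)
        L[:, :, k], valid[:, :, k] = mean_pathlength_image(b, mua, geom)
    return SpectralCube(phi=phi, pathlength=L, valid=valid, wavelengths=lams,
                        pitch_mm=geom.pitch_mm)


def spatial_binning(cube: SpectralCube, factor: int) -> SpectralCube:
    """Bin pixels factor x factor; phi by mean density, L weighted by phi.

    The output pixel pitch is ``factor`` times the input pitch; trailing
    rows/columns that do not fill a block are truncated.
    """
    if factor < 1:
        raise ValueError("binning factor must be >= 1")
    if factor == 1:
        return cube
    ny, nx, nl = cube.phi.shape
    my, mx = ny // factor, nx // factor
    if my < 1 or mx < 1:
        raise ValueError("binning factor larger than the image")
    phi = cube.phi[:my * factor, :mx * factor]
    L = cube.pathlength[:my * factor, :mx * factor]
    blocks = phi.reshape(my, factor, mx, factor, nl)
    lblocks = L.reshape(my, factor, mx, factor, nl)
    phi_b = blocks.mean(axis=(1, 3))
    wsum = blocks.sum(axis=(1, 3))
    pwsum = (blocks * lblocks).sum(axis=(1, 3))
    valid = wsum > 0
    L_b = np.zeros_like(phi_b)
    L_b[valid] = pwsum[valid] / wsum[valid]
    return SpectralCube(phi=phi_b, pathlength=L_b, valid=valid,
                        wavelengths=cube.wavelengths,
                        pitch_mm=cube.pitch_mm * factor,
                        bin_factor=cube.bin_factor * factor,
                        meta=dict(cube.meta))


def denoise_nlm(cube: SpectralCube, h_factor: float = 0.8,
                patch_size: int = 3, patch_distance: int = 5) -> SpectralCube:
    """Per-wavelength non-local-means filtering of phi and L.

    The filter strength adapts to each wavelength through the estimated
    noise level; ``h_factor = 0`` is the identity.
    """
    if h_factor == 0.0:
        return cube
    phi = np.empty_like(cube.phi)
    L = np.empty_like(cube.pathlength)
    for k in range(cube.wavelengths.size):
        for src, dst in ((cube.phi, phi), (cube.pathlength, L)):
            img = src[:, :, k]
            sigma = float(estimate_sigma(img))
            if sigma == 0.0:
                dst[:, :, k] = img
                continue
            dst[:, :, k] = denoise_nl_means(
                img, h=h_factor * sigma, sigma=sigma, fast_mode=True,
                patch_size=patch_size, patch_distance=patch_distance)
    np.clip(phi, 0.0, None, out=phi)
    np.clip(L, 0.0, None, out=L)
    return SpectralCube(phi=phi, pathlength=L, valid=cube.valid.copy(),
                        wavelengths=cube.wavelengths, pitch_mm=cube.pitch_mm,
                        bin_factor=cube.bin_factor, meta=dict(cube.meta))


def interpolate_cube(cube: SpectralCube, grid=None) -> SpectralCube:
    """Linear per-pixel spectral interpolation onto a 1-nm grid."""
    if grid is None:
        grid = np.arange(cube.wavelengths.min(), cube.wavelengths.max() + 0.5, 1.0)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < cube.wavelengths.min() or grid.max() > cube.wavelengths.max():
        raise ValueError("grid requests spectral extrapolation")
    ny, nx, _ = cube.phi.shape
    idx = np.searchsorted(cube.wavelengths, grid, side="right") - 1
    idx = np.clip(idx, 0, cube.wavelengths.size - 2)
    lam0 = cube.wavelengths[idx]
    lam1 = cube.wavelengths[idx + 1]
    t = (grid - lam0) / (lam1 - lam0)
    phi = cube.phi[:, :, idx] * (1 - t) + cube.phi[:, :, idx + 1] * t
    L = (cube.pathlength[:, :, idx] * (1 - t)
         + cube.pathlength[:, :, idx + 1] * t)
    valid = cube.valid[:, :, idx] & cube.valid[:, :, idx + 1]
    return SpectralCube(phi=phi, pathlength=L, valid=valid, wavelengths=grid,
                        pitch_mm=cube.pitch_mm, bin_factor=cube.bin_factor,
                        meta=dict(cube.meta))


def pooled_spectra(cube: SpectralCube, mask: np.ndarray):
    """Treat a pixel region as one super-pixel: pooled phi and L spectra.

    phi pools as the mean weight density over the region; L pools as the
    phi-weighted mean, which equals re-evaluating the estimator on the
    merged pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.phi.shape[:2]:
        raise ValueError("mask shape does not match the cube")
    phi_r = cube.phi[mask]              # (n_px, n_lambda)
    L_r = cube.pathlength[mask]
    phi = phi_r.mean(axis=0)
    wsum = phi_r.sum(axis=0)
    L = np.zeros_like(phi)
    nz = wsum > 0
    L[nz] = (phi_r * L_r).sum(axis=0)[nz] / wsum[nz]
    return phi, L
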