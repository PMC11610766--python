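"""White (zero-absorption) voxel Monte Carlo photon transport.

One transport run per wavelength records, for every photon refracted out of
the top face, its exit position, its paraxial exit angles and the partial
path length it accumulated in each labeled tissue region.  Because no
absorption is applied during transport, the same photon records can be
reweighted a posteriori for any absorption scenario (microscopic
Beer-Lambert law) - one simulation serves every chemical composition and
every activation state at that wavelength.

An analog absorbing engine (:func:`run_absorbing_mc`) is also provided; it
decides absorption photon-by-photon at each interaction instead of
reweighting, and serves as an independent cross-check of the white-MC
reweighting chain.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np

from . import _kernels
from .spectra import TissueOptics
from .volume import LabelVolume

__all__ = [
    "SimulationConfig",
    "PhotonBatch",
    "fresnel_reflectance",
    "run_white_mc",
    "run_absorbing_mc",
    "save_batches",
    "load_batches",
]


def default_wavelengths() -> np.ndarray:
    """Simulated wavelength grid: 400-1000 nm in 10-nm steps."""
    return np.arange(400.0, 1000.0 + 1e-9, 10.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Transport run parameters.

    ``max_path_mm`` caps runaway trajectories (photons exceeding it are
    discarded and counted); lateral boundaries are always cyclic, the top
    and bottom faces are Fresnel interfaces against ``ambient_n``.
    """

    n_photons: int = 100_000
    wavelengths: np.ndarray = field(default_factory=default_wavelengths)
    seed: int = 0
    ambient_n: float = 1.0
    internal_mismatch: bool = True
    specular_at_launch: bool = False
    max_path_mm: float = 10_000.0

    def __post_init__(self):
        if self.n_photons < 1:
            raise ValueError("need at least one photon")
        lam = np.asarray(self.wavelengths, dtype=float)
        if np.any(lam < 400.0) or np.any(lam > 1000.0):
            raise ValueError("wavelengths outside the simulated 400-1000 nm range")


@dataclass
class PhotonBatch:
    """Detected-photon records of one transport run at one wavelength."""

    wavelength: float
    n_launched: int
    exit_x: np.ndarray          # mm on the top face, along the volume's
    exit_y: np.ndarray          # first / second array axis respectively
    theta_x: np.ndarray         # rad, paraxial exit angles in ambient
    theta_y: np.ndarray
    ppl: np.ndarray             # (n_detected, n_regions) partial paths, mm
    total_path: np.ndarray      # mm, geometric trajectory length
    region_names: tuple[str, ...]
    seed: int
    n_lost_bottom: int = 0
    n_lost_cap: int = 0
    n_lost_specular: int = 0
    n_absorbed: int = 0

    @property
    def n_detected(self) -> int:
        return self.exit_x.shape[0]

    @property
    def detected_fraction(self) -> float:
        return self.n_detected / self.n_launched


def fresnel_reflectance(n1: float, n2: float, cos_incident: float) -> float:
    """Unpolarized Fresnel reflectance at a planar interface.

    Returns 1 beyond the critical angle; ``cos_incident`` must be in (0, 1].
    """
    if cos_incident <= 0.0 or cos_incident > 1.0:
        raise ValueError("cos of the incidence angle must be in (0, 1]")
    if n1 < 1.0 or n2 < 1.0:
        raise ValueError("refractive indices below 1 are not supported")
    return float(_kernels.fresnel_reflectance_kernel(n1, n2, cos_incident))


def _class_tables(vol: LabelVolume, optics: Mapping[str, TissueOptics],
                  wavelength: float):
    present = np.unique(vol.labels)
    mus = np.empty(vol.n_regions)
    g = np.empty(vol.n_regions)
    n = np.empty(vol.n_regions)
    for idx, name in enumerate(vol.class_names):
        if name not in optics:
            if idx in present:
                raise KeyError(
                    f"tissue class {name!r} present in the volume has no "
                    f"optical properties")
            mus[idx], g[idx], n[idx] = 1.0, 0.0, 1.0
            continue
        opt = optics[name]
        mus[idx] = opt.mus(wavelength)
        g[idx] = opt.g
        n[idx] = opt.n
    if np.any(mus <= 0):
        raise ValueError("scattering coefficient must be positive")
    return mus, g, n


def _run(vol: LabelVolume, coeff, g, n, absorb_prob, cfg: SimulationConfig,
         wavelength: float, seed: int) -> PhotonBatch:
    n_ph = cfg.n_photons
    nreg = vol.n_regions
    exit_x = np.empty(n_ph)
    exit_y = np.empty(n_ph)
    theta_x = np.empty(n_ph)
    theta_y = np.empty(n_ph)
    ppl = np.empty((n_ph, nreg))
    total_path = np.empty(n_ph)
    n_det, n_bottom, n_cap, n_spec, n_abs = _kernels.trace_photons(
        vol.labels, coeff, g, n, absorb_prob, cfg.ambient_n, vol.pitch_mm,
        n_ph, seed, cfg.max_path_mm, cfg.internal_mismatch,
        cfg.specular_at_launch,
        exit_x, exit_y, theta_x, theta_y, ppl, total_path)
    return PhotonBatch(
        wavelength=float(wavelength),
        n_launched=n_ph,
        exit_x=exit_x[:n_det].copy(),
        exit_y=exit_y[:n_det].copy(),
        theta_x=theta_x[:n_det].copy(),
        theta_y=theta_y[:n_det].copy(),
        ppl=ppl[:n_det].copy(),
        total_path=total_path[:n_det].copy(),
        region_names=vol.class_names,
        seed=seed,
        n_lost_bottom=n_bottom,
        n_lost_cap=n_cap,
        n_lost_specular=n_spec,
        n_absorbed=n_abs,
    )


def _wavelength_seed(base_seed: int, wavelength: float) -> int:
    # sub-2^31 deterministic per-wavelength stream offset
    return (int(base_seed) * 1_000_003 + int(round(wavelength * 10))) % (2**31 - 1)


def run_white_mc(vol: LabelVolume, optics: Mapping[str, TissueOptics],
                 cfg: SimulationConfig) -> dict[float, PhotonBatch]:
    """White Monte Carlo transport; returns one PhotonBatch per wavelength."""
    out: dict[float, PhotonBatch] = {}
    absorb = np.zeros(vol.n_regions)
    for lam in np.asarray(cfg.wavelengths, dtype=float):
        mus, g, n = _class_tables(vol, optics, lam)
        out[float(lam)] = _run(vol, mus, g, n, absorb, cfg, lam,
                               _wavelength_seed(cfg.seed, lam))
    return out


def run_absorbing_mc(vol: LabelVolume, optics: Mapping[str, TissueOptics],
                     mua_by_region: Sequence[float],
                     cfg: SimulationConfig,
                     wavelength: float = 500.0) -> PhotonBatch:
    """Analog absorbing Monte Carlo at a single wavelength.

    Free paths are sampled from mu_t = mu_s + mu_a and the photon is
    absorbed with probability mu_a / mu_t at each interaction.  Used as an
    independent oracle for the white-MC reweighting route; the detected
    photons all carry unit weight.
    """
    mua = np.asarray(mua_by_region, dtype=float)
    if mua.shape != (vol.n_regions,):
        raise ValueError("need one absorption coefficient per region")
    if np.any(mua < 0):
        raise ValueError("absorption coefficients must be >= 0")
    mus, g, n = _class_tables(vol, optics, wavelength)
    mut = mus + mua
    absorb = mua / mut
    return _run(vol, mut, g, n, absorb, cfg, wavelength,
                _wavelength_seed(cfg.seed, wavelength))


def save_batches(batches: Mapping[float, PhotonBatch], path: str | Path) -> None:
    """Write detected-photon records to HDF5 (one group per wavelength)."""
    with h5py.File(path, "w") as fh:
        for lam in sorted(batches):
            b = batches[lam]
            grp = fh.create_group(f"wl_{lam:.1f}")
            grp.create_dataset("exit_xy",
                               data=np.column_stack([b.exit_x, b.exit_y]))
            grp.create_dataset("exit_angles",
                               data=np.column_stack([b.theta_x, b.theta_y]))
            grp.create_dataset("ppl", data=b.ppl)
            grp.create_dataset("total_path", data=b.total_path)
            grp.attrs["wavelength"] = b.wavelength
            grp.attrs["n_launched"] = b.n_launched
            grp.attrs["seed"] = b.seed
            grp.attrs["n_lost_bottom"] = b.n_lost_bottom
            grp.attrs["n_lost_cap"] = b.n_lost_cap
            grp.attrs["region_names"] = ",".join(b.region_names)


def load_batches(path: str | Path) -> dict[float, PhotonBatch]:
    out: dict[float, PhotonBatch] = {}
    with h5py.File(path, "r") as fh:
        for key in fh:
            grp = fh[key]
            xy = grp["exit_xy"][...]
            ang = grp["exit_angles"][...]
            b = PhotonBatch(
                wavelength=float(grp.attrs["wavelength"]),
                n_launched=int(grp.attrs["n_launched"]),
                exit_x=xy[:, 0], exit_y=xy[:, 1],
                theta_x=ang[:, 0], theta_y=ang[:, 1],
                ppl=grp["ppl"][...],
                total_path=grp["total_path"][...],
                region_names=tuple(str(grp.attrs["region_names"]).split(",")),
                seed=int(grp.attrs["seed"]),
                n_lost_bottom=int(grp.attrs["n_lost_bottom"]),
                n_lost_cap=int(grp.attrs["n_lost_cap"]),
            )
            out[b.wavelength] = b
    return out
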