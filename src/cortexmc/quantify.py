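"""Modified Beer-Lambert quantification of a simulated cortical activation.

A cortical activation is modeled as a step change of chromophore
concentrations in an activated grey-matter region (default: +5 uM HbO2,
-3.75 uM Hb, +0.5 uM for the oxidized states of CCO and cytochromes b and
c, mirrored by -0.5 uM of their reduced states so total cytochrome content
is conserved).  Because transport is white, the rest and activity
reflectance spectra come from reweighting the same photon records with the
rest and activated absorption coefficients - no new transport run.

Quantification then follows the wide-field NIRS chain:

    dA(lambda) = log10((phi_rest + gamma) / (phi_activity + gamma)),

with gamma zero-mean Gaussian instrument noise of standard deviation
``sigma = phi_rest / SNR`` (shared across wavelengths through the mean rest
reflectance by default), inverted in the least-squares sense through the
design matrix ``A[k, n] = L(lambda_k) eps_n(lambda_k)`` built from the rest
mean path length and the molar extinction spectra (oxidized-minus-reduced
difference spectra for the cytochromes).  Errors are summarized as the
root-mean-square error over noise draws against the ground-truth change.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .spectra import ExtinctionLibrary, TissueComposition

__all__ = [
    "DEFAULT_ACTIVATION_DC_UM",
    "ActivationModel",
    "NoiseModel",
    "MBLLSystem",
    "activated_composition",
    "attenuation_change",
    "mbll_solve",
    "rmse",
    "quantify_noisy",
]

#: ground-truth activation concentration changes, uM
DEFAULT_ACTIVATION_DC_UM = {
    "HbO2": 5.0,
    "Hb": -3.75,
    "oxCCO": 0.5,
    "oxCytb": 0.5,
    "oxCytc": 0.5,
}

#: chromophore name -> extinction-spectrum name used in the design matrix
DESIGN_SPECTRA = {
    "HbO2": "HbO2",
    "Hb": "Hb",
    "oxCCO": "ox-redCCO",
    "oxCytb": "ox-redCytb",
    "oxCytc": "ox-redCytc",
}


@dataclass(frozen=True)
class ActivationModel:
    """Concentration step of the activated region.

    ``dc_uM`` maps chromophore -> change in uM; reduced cytochrome states
    are mirrored automatically.  ``region`` names the volume class whose
    composition is perturbed.
    """

    dc_uM: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVATION_DC_UM))
    region: str = "activated_grey"

    def ground_truth_M(self, chromophores: Sequence[str]) -> np.ndarray:
        return np.array([self.dc_uM.get(c, 0.0) for c in chromophores]) * 1e-6


@dataclass(frozen=True)
class NoiseModel:
    """Instrument noise: sigma = phi_rest / SNR, N_noise independent draws.

    With ``shared_sigma`` a single sigma computed from the mean rest
    reflectance over the used wavelengths is applied to every wavelength;
    otherwise sigma is per-wavelength.
    """

    snr: float = 400.0
    n_noise: int = 1000
    seed: int = 0
    shared_sigma: bool = True

    def __post_init__(self):
        if self.snr <= 0:
            raise ValueError("SNR must be positive")
        if self.n_noise < 1:
            raise ValueError("need at least one noise draw")

    def sigma(self, phi_rest: np.ndarray) -> np.ndarray:
        phi_rest = np.asarray(phi_rest, dtype=float)
        if self.shared_sigma:
            return np.full_like(phi_rest, phi_rest.mean() / self.snr)
        return phi_rest / self.snr


def activated_composition(rest: TissueComposition,
                          act: ActivationModel) -> TissueComposition:
    """Rest composition shifted by the activation concentration changes."""
    return rest.with_concentration_changes(act.dc_uM)


def attenuation_change(phi_rest: np.ndarray, phi_activity: np.ndarray,
                       noise: NoiseModel | None = None,
                       rng: np.random.Generator | None = None,
                       normals: np.ndarray | None = None) -> np.ndarray:
    """Noisy decadic attenuation changes, shape (n_noise, k).

    Independent Gaussian draws are added to the rest and activity
    intensities of each wavelength before the log ratio.  Draws that would
    make an intensity non-positive are redrawn (deterministically, from the
    same stream).  With ``noise=None`` the single noise-free dA row is
    returned.  ``normals`` may supply pre-drawn standard normals of shape
    (n_noise, k, 2) to share one noise realization across evaluations.
    """
    phi_rest = np.atleast_1d(np.asarray(phi_rest, dtype=float))
    phi_activity = np.atleast_1d(np.asarray(phi_activity, dtype=float))
    if np.any(phi_rest <= 0) or np.any(phi_activity <= 0):
        raise ValueError("reflectance must be positive at the used wavelengths")
    if noise is None:
        return np.log10(phi_rest / phi_activity)[None, :]

    k = phi_rest.size
    sigma = noise.sigma(phi_rest)
    if normals is None:
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        normals = rng.standard_normal((noise.n_noise, k, 2))
    num = phi_rest[None, :] + sigma[None, :] * normals[:, :, 0]
    den = phi_activity[None, :] + sigma[None, :] * normals[:, :, 1]
    bad = (num <= 0) | (den <= 0)
    n_redraw = 0
    redraw_rng = np.random.default_rng((noise.seed + 1) * 7919)
    while bad.any():
        n_redraw += int(bad.sum())
        z = redraw_rng.standard_normal((int(bad.sum()), 2))
        num[bad] = phi_rest[None, :].repeat(noise.n_noise, 0)[bad] \
            + np.broadcast_to(sigma, num.shape)[bad] * z[:, 0]
        den[bad] = phi_activity[None, :].repeat(noise.n_noise, 0)[bad] \
            + np.broadcast_to(sigma, den.shape)[bad] * z[:, 1]
        bad = (num <= 0) | (den <= 0)
    return np.log10(num / den)


@dataclass
class MBLLSystem:
    """Design matrix of the modified Beer-Lambert inversion.

    Rows are wavelengths, columns chromophores; entry (k, n) is
    ``L(lambda_k) * eps_n(lambda_k)`` with L in mm and eps in M^-1 mm^-1,
    so solved concentration changes are in M.
    """

    wavelengths: np.ndarray
    chromophores: tuple[str, ...]
    matrix: np.ndarray

    @classmethod
    def build(cls, wavelengths, pathlength_mm, lib: ExtinctionLibrary,
              chromophores: Sequence[str]) -> "MBLLSystem":
        lam = np.atleast_1d(np.asarray(wavelengths, dtype=float))
        L = np.atleast_1d(np.asarray(pathlength_mm, dtype=float))
        if L.shape != lam.shape:
            raise ValueError("need one path length per wavelength")
        if lam.size < len(chromophores):
            raise ValueError("fewer wavelengths than chromophores")
        cols = [lib.epsilon(DESIGN_SPECTRA[c], lam) for c in chromophores]
        A = L[:, None] * np.column_stack(cols)
        return cls(wavelengths=lam, chromophores=tuple(chromophores), matrix=A)

    def check_rank(self) -> None:
        if np.linalg.matrix_rank(self.matrix) < len(self.chromophores):
            raise np.linalg.LinAlgError(
                f"rank-deficient Beer-Lambert design at wavelengths "
                f"{np.round(self.wavelengths, 1).tolist()} for "
                f"chromophores {self.chromophores}")


def mbll_solve(dA: np.ndarray, system: MBLLSystem) -> np.ndarray:
    """Least-squares concentration changes in M; (n_draws, n_chromophores)."""
    system.check_rank()
    dA = np.atleast_2d(np.asarray(dA, dtype=float))
    sol, *_ = np.linalg.lstsq(system.matrix, dA.T, rcond=None)
    return sol.T


def rmse(dc_estimates: np.ndarray, dc_gt: np.ndarray) -> np.ndarray:
    """Per-chromophore root-mean-square error across noise draws (in the
    units of the inputs)."""
    est = np.atleast_2d(np.asarray(dc_estimates, dtype=float))
    gt = np.asarray(dc_gt, dtype=float)
    return np.sqrt(np.mean((est - gt[None, :]) ** 2, axis=0))


def quantify_noisy(phi_rest, phi_activity, pathlength_mm, wavelengths,
                   lib: ExtinctionLibrary, chromophores: Sequence[str],
                   activation: ActivationModel,
                   noise: NoiseModel | None = None,
                   normals: np.ndarray | None = None) -> dict[str, dict[str, float]]:
    """End-to-end noisy quantification at a fixed wavelength set.

    Returns per-chromophore ``rmse_uM``, ``bias_uM`` (mean estimate minus
    ground truth) and ``sd_uM`` across the noise draws.
    """
    system = MBLLSystem.build(wavelengths, pathlength_mm, lib, chromophores)
    dA = attenuation_change(phi_rest, phi_activity, noise, normals=normals)
    dc = mbll_solve(dA, system)
    gt = activation.ground_truth_M(chromophores)
    err = rmse(dc, gt) * 1e6
    mean = dc.mean(axis=0) * 1e6
    sd = dc.std(axis=0) * 1e6
    return {
        c: {"rmse_uM": float(err[i]),
            "bias_uM": float(mean[i] - gt[i] * 1e6),
            "sd_uM": float(sd[i])}
        for i, c in enumerate(chromophores)
    }
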