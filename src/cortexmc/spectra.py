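"""Wavelength-dependent optical properties of cortical tissue.

This module turns chromophore chemistry into the absorption and scattering
coefficients that drive the photon-transport and quantification stages:

* :class:`ExtinctionLibrary` holds molar extinction spectra ``eps_n(lambda)``
  (decadic, M^-1 mm^-1) for HbO2, Hb and the oxidized/reduced states of the
  three mitochondrial cytochromes, plus pure-substance absorption spectra of
  water and fat, all resampled to a 1-nm grid on 400-1000 nm.  The bundled
  tables are synthetic analytic stand-ins for the published compendium
  spectra (see ``scripts/generate_spectra.py``).
* :class:`TissueComposition` holds the chemical make-up of one tissue class
  (water/fat fractions, total hemoglobin and oxygen saturation, cytochrome
  concentrations in uM).
* :func:`absorption_coefficient` composes them into

      mu_a(lambda) = F_water mu_a,water + F_fat mu_a,fat
                     + ln(10) * sum_n eps_n(lambda) C_n        [mm^-1]

  with decadic extinction coefficients and concentrations in M, so that the
  natural-log Beer-Lambert exponential ``exp(-mu_a * path)`` and the decadic
  attenuation used in the modified Beer-Lambert inversion are mutually
  consistent.
* :func:`scattering_coefficient` evaluates the per-class power law
  ``mu_s = a (lambda/500)^-b`` (grey matter: a=4.08 mm^-1, b=3.089;
  blood vessels: a=2.2 mm^-1, b=0.66).
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "WAVELENGTH_MIN",
    "WAVELENGTH_MAX",
    "CHROMOPHORES",
    "DIFFERENCE_CHROMOPHORES",
    "ExtinctionLibrary",
    "TissueComposition",
    "TissueOptics",
    "TISSUE_OPTICS",
    "load_extinction_library",
    "load_tissue_compositions",
    "scattering_coefficient",
    "absorption_coefficient",
    "interpolate_spectrum",
]

WAVELENGTH_MIN = 400.0
WAVELENGTH_MAX = 1000.0

#: chromophores with bundled extinction spectra
CHROMOPHORES = (
    "HbO2", "Hb",
    "oxCCO", "redCCO",
    "oxCytb", "redCytb",
    "oxCytc", "redCytc",
)

#: oxidized-minus-reduced difference spectra used in the MBLL design matrix
DIFFERENCE_CHROMOPHORES = ("ox-redCCO", "ox-redCytb", "ox-redCytc")

_DIFF_PAIRS = {
    "ox-redCCO": ("oxCCO", "redCCO"),
    "ox-redCytb": ("oxCytb", "redCytb"),
    "ox-redCytc": ("oxCytc", "redCytc"),
}

# mu_s power laws, (a [mm^-1 at 500 nm], b)
_SCATTERING_LAWS = {
    "grey_matter": (4.08, 3.089),
    "large_vessel": (2.2, 0.66),
    "small_vessel": (2.2, 0.66),
}
_SCATTERING_ALIASES = {
    "grey matter": "grey_matter",
    "activated_grey": "grey_matter",
    "large vessel": "large_vessel",
    "small vessel": "small_vessel",
    "artery": "large_vessel",
    "vein": "large_vessel",
}


def _resolve_class(name: str) -> str:
    key = _SCATTERING_ALIASES.get(name, name)
    if key not in _SCATTERING_LAWS:
        raise KeyError(f"unknown tissue class {name!r}")
    return key


def scattering_coefficient(tissue_class: str, wavelength_nm) -> np.ndarray | float:
    """mu_s(lambda) = a (lambda/500)^-b in mm^-1 for a tissue class."""
    lam = np.asarray(wavelength_nm, dtype=float)
    if np.any(lam < WAVELENGTH_MIN) or np.any(lam > WAVELENGTH_MAX):
        raise ValueError(
            f"wavelength outside simulated range "
            f"[{WAVELENGTH_MIN:g}, {WAVELENGTH_MAX:g}] nm")
    a, b = _SCATTERING_LAWS[_resolve_class(tissue_class)]
    mus = a * (lam / 500.0) ** (-b)
    return float(mus) if np.isscalar(wavelength_nm) else mus


def interpolate_spectrum(samples: Sequence[tuple[float, float]] | np.ndarray,
                         grid) -> np.ndarray:
    """Piecewise-linear resampling of a tabulated spectrum onto ``grid``.

    ``samples`` is a sorted sequence of (wavelength_nm, value) pairs.
    Extrapolation beyond the sampled range raises, it is never silently
    clamped.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (wavelength, value) samples")
    lam, val = arr[:, 0], arr[:, 1]
    if np.any(np.diff(lam) <= 0):
        raise ValueError("sample wavelengths must be strictly increasing")
    g = np.asarray(grid, dtype=float)
    if np.any(g < lam[0]) or np.any(g > lam[-1]):
        raise ValueError("grid requests extrapolation beyond the sampled range")
    return np.interp(g, lam, val)


@dataclass(frozen=True)
class ExtinctionLibrary:
    """Molar extinction and background absorption spectra on a 1-nm grid.

    ``extinction`` maps chromophore name -> eps(lambda) in M^-1 mm^-1;
    ``background`` maps {'water', 'fat'} -> mu_a(lambda) of the pure
    substance in mm^-1.
    """

    wavelengths: np.ndarray
    extinction: Mapping[str, np.ndarray]
    background: Mapping[str, np.ndarray]

    def __post_init__(self):
        for name, spec in self.extinction.items():
            if spec.shape != self.wavelengths.shape:
                raise ValueError(f"grid mismatch for {name}")
            if np.any(spec < 0):
                raise ValueError(f"negative extinction for {name}")

    def epsilon(self, name: str, wavelength_nm) -> np.ndarray | float:
        """eps(lambda) in M^-1 mm^-1; accepts difference-spectrum names."""
        if name in _DIFF_PAIRS:
            ox, red = _DIFF_PAIRS[name]
            spec = self.extinction[ox] - self.extinction[red]
        elif name in self.extinction:
            spec = self.extinction[name]
        else:
            raise KeyError(f"no extinction spectrum for {name!r}")
        out = interpolate_spectrum(
            np.column_stack([self.wavelengths, spec]), np.atleast_1d(wavelength_nm))
        return float(out[0]) if np.isscalar(wavelength_nm) else out

    def background_mua(self, name: str, wavelength_nm) -> np.ndarray | float:
        spec = self.background[name]
        out = interpolate_spectrum(
            np.column_stack([self.wavelengths, spec]), np.atleast_1d(wavelength_nm))
        return float(out[0]) if np.isscalar(wavelength_nm) else out


@dataclass(frozen=True)
class TissueComposition:
    """Chemical composition of one tissue class.

    Fractions are dimensionless in [0, 1]; concentrations are in uM.
    Hemoglobin is parameterized by total concentration and oxygen
    saturation; the oxy/deoxy split is derived
    (``C_HbO2 = SatO2 * C_HbT``, ``C_Hb = (1 - SatO2) * C_HbT``).
    """

    f_water: float = 0.0
    f_fat: float = 0.0
    c_hbt_uM: float = 0.0
    sat_o2: float = 0.0
    c_oxcco_uM: float = 0.0
    c_redcco_uM: float = 0.0
    c_oxcytb_uM: float = 0.0
    c_redcytb_uM: float = 0.0
    c_oxcytc_uM: float = 0.0
    c_redcytc_uM: float = 0.0

    def __post_init__(self):
        for name in ("f_water", "f_fat", "sat_o2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("c_hbt_uM", "c_oxcco_uM", "c_redcco_uM", "c_oxcytb_uM",
                     "c_redcytb_uM", "c_oxcytc_uM", "c_redcytc_uM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def c_hbo2_uM(self) -> float:
        return self.sat_o2 * self.c_hbt_uM

    @property
    def c_hb_uM(self) -> float:
        return (1.0 - self.sat_o2) * self.c_hbt_uM

    def concentrations_uM(self) -> dict[str, float]:
        """Per-chromophore concentrations in uM (oxy/deoxy split applied)."""
        return {
            "HbO2": self.c_hbo2_uM,
            "Hb": self.c_hb_uM,
            "oxCCO": self.c_oxcco_uM,
            "redCCO": self.c_redcco_uM,
            "oxCytb": self.c_oxcytb_uM,
            "redCytb": self.c_redcytb_uM,
            "oxCytc": self.c_oxcytc_uM,
            "redCytc": self.c_redcytc_uM,
        }

    def with_concentration_changes(self, dc_uM: Mapping[str, float]) -> "TissueComposition":
        """New composition with chromophore concentrations shifted by dc_uM.

        Keys are chromophore names.  ``HbO2``/``Hb`` shifts are folded back
        into (C_HbT, SatO2); a shift of an oxidized cytochrome may be given
        alone, in which case the reduced state is mirrored (total cytochrome
        concentration is conserved), or both states may be given explicitly.
        """
        conc = self.concentrations_uM()
        mirrored = dict(dc_uM)
        for ox, red in (("oxCCO", "redCCO"), ("oxCytb", "redCytb"),
                        ("oxCytc", "redCytc")):
            if ox in mirrored and red not in mirrored:
                mirrored[red] = -mirrored[ox]
        for name, dc in mirrored.items():
            if name not in conc:
                raise KeyError(f"unknown chromophore {name!r}")
            conc[name] = conc[name] + dc
            if conc[name] < 0:
                raise ValueError(f"concentration of {name} would become negative")
        hbt = conc["HbO2"] + conc["Hb"]
        sat = conc["HbO2"] / hbt if hbt > 0 else 0.0
        return replace(
            self, c_hbt_uM=hbt, sat_o2=sat,
            c_oxcco_uM=conc["oxCCO"], c_redcco_uM=conc["redCCO"],
            c_oxcytb_uM=conc["oxCytb"], c_redcytb_uM=conc["redCytb"],
            c_oxcytc_uM=conc["oxCytc"], c_redcytc_uM=conc["redCytc"])


def absorption_coefficient(comp: TissueComposition,
                           lib: ExtinctionLibrary,
                           wavelength_nm) -> np.ndarray | float:
    """Tissue absorption coefficient mu_a(lambda) in mm^-1.

    mu_a = F_water mu_a,water + F_fat mu_a,fat + ln(10) sum_n eps_n C_n
    with eps in M^-1 mm^-1 (decadic) and C in M (converted from uM).
    """
    lam = np.atleast_1d(np.asarray(wavelength_nm, dtype=float))
    mua = np.zeros_like(lam)
    if comp.f_water:
        mua += comp.f_water * lib.background_mua("water", lam)
    if comp.f_fat:
        mua += comp.f_fat * lib.background_mua("fat", lam)
    for name, c_uM in comp.concentrations_uM().items():
        if c_uM == 0.0:
            continue
        if name not in lib.extinction:
            raise KeyError(
                f"chromophore {name!r} has nonzero concentration but no "
                f"extinction spectrum in the library")
        mua += np.log(10.0) * lib.epsilon(name, lam) * (c_uM * 1e-6)
    return float(mua[0]) if np.isscalar(wavelength_nm) else mua


@dataclass(frozen=True)
class TissueOptics:
    """Transport parameters of one tissue class.

    ``scatter_class`` selects the mu_s power law, ``g`` is the
    Henyey-Greenstein anisotropy, ``n`` the refractive index, and
    ``composition`` the chemistry used for a-posteriori absorption.
    """

    scatter_class: str
    g: float
    n: float
    composition: TissueComposition = field(default_factory=TissueComposition)

    def mus(self, wavelength_nm):
        return scattering_coefficient(self.scatter_class, wavelength_nm)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("cortexmc").joinpath("data", name)))


def _read_spectrum_csv(path: Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#") or row[0] == "wavelength_nm":
                continue
            rows.append((float(row[0]), float(row[1])))
    return np.asarray(rows, dtype=float)


def load_extinction_library(data_dir: str | Path | None = None) -> ExtinctionLibrary:
    """Load the bundled spectra, resampled to the 1-nm grid 400-1000 nm."""
    base = Path(data_dir) if data_dir is not None else _data_path("")
    with open(base / "spectra_manifest.json") as fh:
        manifest = json.load(fh)
    grid = np.arange(WAVELENGTH_MIN, WAVELENGTH_MAX + 0.5, 1.0)

    def load(entry, to_mm: bool):
        table = _read_spectrum_csv(base / entry["file"])
        scale = 0.1 if entry["units"].endswith("cm^-1") else 1.0
        return interpolate_spectrum(table, grid) * scale

    ext = {name: load(entry, True)
           for name, entry in manifest["extinction"].items()}
    bg = {name: load(entry, True)
          for name, entry in manifest["background"].items()}
    return ExtinctionLibrary(wavelengths=grid, extinction=ext, background=bg)


def load_tissue_compositions(path: str | Path | None = None
                             ) -> dict[str, TissueComposition]:
    """Nominal compositions of grey matter, arteries and veins."""
    p = Path(path) if path is not None else _data_path("tissues.json")
    with open(p) as fh:
        raw = json.load(fh)
    return {name: TissueComposition(**fields) for name, fields in raw.items()}


def default_tissue_optics(vessels: str = "artery") -> dict[str, TissueOptics]:
    """Per-class transport parameters + chemistry for the standard model.

    ``vessels`` selects whether segmented vessels are treated as arteries
    or veins (the imaging geometry cannot distinguish them).
    """
    if vessels not in ("artery", "vein"):
        raise ValueError("vessels must be 'artery' or 'vein'")
    comps = load_tissue_compositions()
    return {
        "grey_matter": TissueOptics("grey_matter", 0.85, 1.36, comps["grey_matter"]),
        "large_vessel": TissueOptics("large_vessel", 0.935, 1.4, comps[vessels]),
        "small_vessel": TissueOptics("small_vessel", 0.935, 1.4, comps[vessels]),
        "activated_grey": TissueOptics("grey_matter", 0.85, 1.36, comps["grey_matter"]),
    }


#: transport parameters without chemistry, keyed by class (Table-style defaults)
TISSUE_OPTICS = {
    "grey_matter": TissueOptics("grey_matter", 0.85, 1.36),
    "large_vessel": TissueOptics("large_vessel", 0.935, 1.4),
    "small_vessel": TissueOptics("small_vessel", 0.935, 1.4),
}
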