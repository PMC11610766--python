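"""Regenerate the bundled synthetic chromophore spectra tables.

The package ships molar-extinction spectra for the eight chromophores
(HbO2, Hb and the oxidized/reduced states of cytochrome-c-oxidase and of
cytochromes b and c) plus pure-substance absorption spectra of water and
fat.  The published compendium tables (Prahl/UCL-style) are plotted, not
tabulated, in the sources this model follows, so the bundled tables are
SYNTHETIC analytic stand-ins: log-linear anchor tables for the hemoglobins,
water and fat, and sums of Gaussian bands for the cytochromes, all pinned
to the well-known band positions and magnitudes (Soret / Q / alpha bands,
the oxCCO 830-nm band, the water 970-nm and lipid 930-nm peaks).  They
reproduce the qualitative spectroscopy that drives the simulator -- band
locations, isobestic regions, orders of magnitude -- not any specific
laboratory dataset.

Run from the repository root:

    python scripts/generate_spectra.py
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

DATA_DIR = Path(__file__).resolve().parents[1] / "src" / "cortexmc" / "data"
GRID = np.arange(400.0, 1000.0 + 1e-9, 2.0)  # nm


def gauss(lam: np.ndarray, amp: float, center: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((lam - center) / sigma) ** 2)


HBO2_ANCHORS = [  # (nm, M^-1 cm^-1): Soret 414, Q bands 542/577, NIR rise
    (400, 266000), (406, 450000), (414, 524000), (420, 411000),
    (426, 220000), (432, 110000), (440, 70000), (450, 62800),
    (460, 44500), (470, 33200), (480, 26600), (490, 23000),
    (500, 20900), (510, 20000), (520, 24200), (530, 39000),
    (535, 47000), (542, 57500), (548, 50000), (555, 38000),
    (560, 32600), (565, 35000), (570, 44900), (577, 64500),
    (584, 50000), (590, 26600), (596, 7500), (600, 3200),
    (605, 2000), (610, 1500), (620, 942), (630, 610), (640, 442),
    (650, 368), (660, 319), (680, 290), (700, 290), (720, 334),
    (740, 446), (760, 586), (780, 710), (800, 816), (820, 916),
    (840, 1022), (860, 1092), (880, 1154), (900, 1198), (920, 1234),
    (940, 1214), (960, 1194), (980, 1130), (1000, 1058),
]

HB_ANCHORS = [  # (nm, M^-1 cm^-1): Soret 430, alpha 555, 760-nm band
    (400, 223000), (410, 304000), (420, 390000), (425, 470000),
    (430, 553000), (435, 500000), (440, 392000), (445, 240000),
    (450, 103300), (460, 71800), (470, 45000), (480, 33200),
    (490, 25000), (500, 20900), (510, 22000), (520, 25800),
    (530, 35000), (540, 46600), (548, 51000), (555, 55500),
    (560, 53400), (570, 45100), (577, 40000), (580, 37000),
    (590, 28300), (600, 14700), (610, 9440), (620, 6510),
    (630, 5150), (640, 4350), (650, 3750), (660, 3230), (680, 2410),
    (700, 1800), (720, 1470), (740, 1340), (750, 1410), (760, 1670),
    (770, 1530), (780, 1350), (790, 1060), (800, 762), (820, 710),
    (840, 690), (850, 692), (880, 730), (900, 762), (920, 780),
    (940, 800), (960, 740), (980, 650), (1000, 550),
]


def hbo2(lam):
    """Oxyhemoglobin molar extinction, M^-1 cm^-1 (anchor table)."""
    return from_anchors(lam, HBO2_ANCHORS)


def hb(lam):
    """Deoxyhemoglobin molar extinction, M^-1 cm^-1 (anchor table)."""
    return from_anchors(lam, HB_ANCHORS)


def ox_cco(lam):
    e = gauss(lam, 120000, 422, 13)
    e += gauss(lam, 5200, 598, 28)
    e += gauss(lam, 3000, 830, 75)           # broad oxidized Cu_A NIR band
    return e + 400


def red_cco(lam):
    e = gauss(lam, 170000, 444, 12)
    e += gauss(lam, 21000, 605, 10)          # reduced heme-a alpha band
    return e + 300


def ox_cytb(lam):
    e = gauss(lam, 110000, 418, 12)
    e += gauss(lam, 9000, 560, 26)
    return e + 300


def red_cytb(lam):
    e = gauss(lam, 160000, 429, 9)
    e += gauss(lam, 11000, 530, 10)
    e += gauss(lam, 27000, 562, 7)           # alpha band
    return e + 200


def ox_cytc(lam):
    e = gauss(lam, 100000, 410, 11)
    e += gauss(lam, 9500, 528, 20)
    e += gauss(lam, 1100, 695, 16)           # oxidized 695-nm charge-transfer band
    return e + 300


def red_cytc(lam):
    e = gauss(lam, 125000, 416, 9)
    e += gauss(lam, 15000, 521, 9)           # beta band
    e += gauss(lam, 28000, 550, 6)           # alpha band
    return e + 200


WATER_ANCHORS = [  # (nm, cm^-1), pure water
    (400, 0.00058), (420, 0.00046), (440, 0.00036), (460, 0.00031),
    (480, 0.00031), (500, 0.00035), (520, 0.00048), (540, 0.00070),
    (560, 0.00090), (580, 0.00120), (600, 0.00230), (620, 0.00280),
    (640, 0.00310), (660, 0.00360), (680, 0.00450), (700, 0.00600),
    (720, 0.01150), (740, 0.02350), (750, 0.02620), (760, 0.02560),
    (780, 0.02360), (800, 0.02060), (820, 0.02630), (840, 0.04340),
    (860, 0.05150), (880, 0.05800), (900, 0.06790), (920, 0.11000),
    (940, 0.26700), (960, 0.42000), (970, 0.45000), (980, 0.43000),
    (1000, 0.36000),
]

FAT_ANCHORS = [  # (nm, cm^-1), pure lipid
    (400, 0.0130), (450, 0.0065), (500, 0.0045), (550, 0.0035),
    (600, 0.0030), (650, 0.0028), (700, 0.0030), (750, 0.0040),
    (760, 0.0065), (770, 0.0050), (800, 0.0045), (850, 0.0055),
    (900, 0.0085), (920, 0.0220), (930, 0.0950), (940, 0.0600),
    (960, 0.0300), (980, 0.0280), (1000, 0.0320),
]


def from_anchors(lam, anchors):
    """Log-linear interpolation between anchors (smooth positive curve)."""
    x = np.array([a[0] for a in anchors], float)
    y = np.log(np.array([a[1] for a in anchors], float))
    return np.exp(np.interp(lam, x, y))


def write_csv(path: Path, lam: np.ndarray, val: np.ndarray, comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# synthetic analytic spectrum: {comment}\n")
        fh.write("wavelength_nm,value\n")
        for w, v in zip(lam, val):
            fh.write(f"{w:.0f},{v:.6g}\n")


def main() -> None:
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    ext = {
        "HbO2": (hbo2, "oxyhemoglobin molar extinction"),
        "Hb": (hb, "deoxyhemoglobin molar extinction"),
        "oxCCO": (ox_cco, "oxidized cytochrome-c-oxidase molar extinction"),
        "redCCO": (red_cco, "reduced cytochrome-c-oxidase molar extinction"),
        "oxCytb": (ox_cytb, "oxidized cytochrome b molar extinction"),
        "redCytb": (red_cytb, "reduced cytochrome b molar extinction"),
        "oxCytc": (ox_cytc, "oxidized cytochrome c molar extinction"),
        "redCytc": (red_cytc, "reduced cytochrome c molar extinction"),
    }
    manifest = {"extinction": {}, "background": {}}
    for name, (fn, desc) in ext.items():
        fname = f"ext_{name.lower()}_synthetic.csv"
        write_csv(DATA_DIR / fname, GRID, fn(GRID), f"{desc}, M^-1 cm^-1")
        manifest["extinction"][name] = {"file": fname, "units": "M^-1 cm^-1"}

    write_csv(DATA_DIR / "mua_water_synthetic.csv", GRID,
              from_anchors(GRID, WATER_ANCHORS),
              "pure water absorption coefficient, cm^-1")
    manifest["background"]["water"] = {
        "file": "mua_water_synthetic.csv", "units": "cm^-1"}
    write_csv(DATA_DIR / "mua_fat_synthetic.csv", GRID,
              from_anchors(GRID, FAT_ANCHORS),
              "pure lipid absorption coefficient, cm^-1")
    manifest["background"]["fat"] = {
        "file": "mua_fat_synthetic.csv", "units": "cm^-1"}

    with open(DATA_DIR / "spectra_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    print(f"wrote {len(ext) + 2} spectra + manifest to {DATA_DIR}")


if __name__ == "__main__":
    main()
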