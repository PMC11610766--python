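# Methods

This note documents the models implemented in `cortexmc`, the defaults and
why they were chosen, the numerical decisions that affect results, and what
the synthetic fixtures do and do not establish about real data.

## Tissue model

Three tissue classes are modeled — grey matter, large blood vessels
(surface width >= 0.5 mm) and small blood vessels — plus, for activation
studies, an `activated_grey` region that shares grey-matter optics but is
tracked as its own partial-path channel.

Transport parameters per class:

| class        | mu_s (mm^-1)             | g     | n    |
|--------------|--------------------------|-------|------|
| grey matter  | 4.08 (lambda/500)^-3.089 | 0.85  | 1.36 |
| vessels      | 2.2 (lambda/500)^-0.66   | 0.935 | 1.4  |

Chemistry per class (water/fat volume fractions; concentrations in uM;
hemoglobin given as total concentration and oxygen saturation, with
C_HbO2 = SatO2 * C_HbT):

| field        | grey matter | artery | vein |
|--------------|-------------|--------|------|
| F_water      | 0.73        | 0.55   | 0.55 |
| F_fat        | 0.10        | 0.01   | 0.01 |
| C_HbT (uM)   | 76          | 2324   | 2324 |
| SatO2        | 0.85        | 0.98   | 0.60 |
| oxCCO/redCCO | 6.4 / 1.6   | 0      | 0    |
| oxCytb/redCytb | 2.37 / 0.89 | 0    | 0    |
| oxCytc/redCytc | 1.36 / 0.68 | 0    | 0    |

The absorption coefficient composes as

    mu_a(lambda) = F_water mu_a,water + F_fat mu_a,fat
                   + ln(10) * sum_n eps_n(lambda) C_n   [mm^-1],

with decadic molar extinction coefficients eps in M^-1 mm^-1 and
concentrations in M.  The ln(10) factor makes the natural-log transport
weight `exp(-mu_a * path)` consistent with the decadic attenuation used in
the modified Beer-Lambert inversion.  No baseline absorber beyond water and
fat is included.

### Spectra provenance

The bundled extinction and background tables
(`src/cortexmc/data/*_synthetic.csv`) are **synthetic analytic stand-ins**,
generated by `scripts/generate_spectra.py`: the hemoglobins are log-linear
anchor tables reproducing the compendium band structure (Soret bands at
414/430 nm, Q/alpha bands at 542/577 and 555 nm, the Hb 760-nm band, the
near-isobestic points near 500 and ~800 nm, the NIR crossover); the six
cytochrome states are sums of Gaussian bands at their classical Soret /
alpha / charge-transfer positions, including the broad oxidized-CCO band
near 830 nm; water and fat are anchor tables with the 970-nm and 930-nm
peaks.  Oxidized-minus-reduced difference spectra are computed exactly from
the ox/red tables, never tabulated separately, so redox bookkeeping and
difference-spectrum inversion are algebraically identical (this is a tested
invariant).

Consequences: sanity contrasts land on the expected scale (the mean
artery-minus-grey-matter absorption contrast over 400-1000 nm evaluates to
~160 cm^-1 with these tables), and all sign/ordering physics is faithful,
but absolute chromophore-error figures should be compared with published
numbers only in scale and ranking.

## Segmentation

The five-step morphological chain: luma grayscale (0.299 R + 0.587 G +
0.114 B); Gaussian adaptive threshold with a 5-mm block converted to an odd
pixel count (`ceil(5 / 0.073) = 69` px at 73 um) and polarity "pixel <
local mean − offset" (vessels are darker), offset 2 grey levels; specular
pixels excluded at grayscale >= 250; opening then closing with a 0.5-mm
digital disk (7 px at 73 um) gives the large-vessel mask; the xor with the
thresholded image gives the small vessels; the window remainder is grey
matter.  Because closing can add pixels outside the thresholded set, the
small-vessel mask is additionally clipped against the large-vessel mask so
the three masks stay pairwise disjoint — the partition invariant is
asserted on every call.  The surgical-window mask is an input, not
computed; threshold polarity, offset and specular cutoff are configuration
with the defaults above.

## Volume modeling

Masks are padded laterally with grey matter (default 10% of each dimension)
so no vessel touches a boundary voxel, then extruded to 20 mm depth at the
image pitch (isotropic voxels).  Vessel cross-sections at depth-slice z are
the surface mask eroded by a digital disk of radius `round(z / taper)`;
with the default `taper = 1` slice per pixel a vessel of surface width w
vanishes at depth ~w/2 — vessel thickness follows vessel diameter.  The
exact per-slice growth rate is not uniquely determined by the narrative
this model follows, so it is a configuration parameter.  Deep vessels not
visible at the surface are not generated.  Volumes round-trip through a raw
uint8 + JSON header format (pynrrd is not a dependency).

## White Monte Carlo transport

Single-photon random walks (with zero absorption a survival weight is
identically 1, so weighted packets reduce to single photons; the "packet"
vocabulary survives only in the data model).  Photons launch uniformly over
the top face heading straight down; free paths are sampled from mu_s of the
current voxel class; scattering is Henyey-Greenstein with the class g;
voxel traversal steps exactly to voxel faces, and the remaining sampled
path is rescaled by the mu_s ratio when the class changes across a face.
Refractive mismatch is applied with unpolarized Fresnel
reflection/refraction (including total internal reflection) at the top and
bottom faces against ambient n = 1, and — by default, switchable — at
internal vessel/grey interfaces (1.4 vs 1.36).  Lateral boundaries are
cyclic.  Photons refracted out of the top face are recorded (exit position,
paraxial angles theta_x = atan(u_x / cos_t), per-region partial paths);
photons leaving the bottom are lost; trajectories beyond `max_path_mm`
(default 10^4 mm) are discarded and counted.

Numerical details: positions and voxel indices are tracked jointly, with
the voxel walls always derived from the integer indices so face hits cannot
drift; the wall-distance computation clamps at zero against floating-point
backsteps.  The RNG is counter-based: each photon's stream is an
xorshift64* sequence seeded by splitmix64 over (seed, photon id), so photon
i is bit-identical regardless of the launch count — the prefix property is
tested, and fixed seeds give bit-identical batches.  Specular reflection at
launch is off by default (the source is treated as inside the medium) and
available as configuration.

An analog absorbing engine (free paths from mu_t, absorption decided
per-interaction with probability mu_a/mu_t) provides an independent oracle:
the detected weight fraction of the reweighted white run must agree with
the analog detected fraction within combined Monte Carlo standard errors.

## Image reconstruction

Per pixel, phi = sum of detected weights / (N_launched * A_p) in mm^-2 per
launched photon, and L = the weight-averaged total geometric path.  Pixels
with no detected photon carry L = 0 plus an explicit validity mask (never
NaN), so downstream consumers behave deterministically.  Lens mode applies
the 2x2 ray-transfer matrix `S = T_s L_f0 T_d0` independently to (x,
theta_x) and (y, theta_y); the negative magnification at the imaging
condition is kept (the image is inverted, no flip).  Photons mapping
off-sensor are dropped and counted; no aperture/NA cutoff is applied by
default.  Spatial binning averages phi as a weight density and pools L
phi-weighted, which is provably identical to re-evaluating the estimators
on the coarse grid (tested).  An optional per-wavelength non-local-means
filter (scikit-image, strength scaled to the estimated noise level) is off
by default in tests.  Spectral interpolation to the 1-nm grid is linear per
pixel and refuses extrapolation.

## Activation and quantification

The activation adds (+5, -3.75, +0.5, +0.5, +0.5) uM to (HbO2, Hb, oxCCO,
oxCytb, oxCytc) in the activated region, mirroring the reduced cytochrome
states by -0.5 uM so each cytochrome's total is conserved.  Because
transport is white, the rest and activity reflectances come from reweighting
the same photon records — no second simulation.

Noise: gamma is zero-mean Gaussian with sigma = phi_rest / SNR, SNR = 400,
N_noise = 1000 draws.  A single sigma, computed from the mean rest
reflectance over the wavelengths in use, is shared across wavelengths
(default); a per-wavelength sigma mode exists.  The numerator and
denominator draws of each attenuation change are independent; draws that
would make an intensity non-positive are redrawn from a dedicated stream
(deterministic, counted).

The design matrix uses the rest-state path length L(lambda) (the only state
available before an activation in practice) and the extinction spectra of
the chromophore subset, with oxidized-minus-reduced difference spectra for
the cytochromes; the least-squares solution is reported in uM, with RMSE,
bias and standard deviation over the noise draws.  For optimization
contexts the evaluated region is pooled into one super-pixel (mean phi,
phi-weighted L) over the central activated surface, one millimetre away
from the partial-volume edge; per-pixel evaluation remains available
through the cube API.

Two accuracy limits are inherent and tested as such: (i) the inversion is
exact only to first order in the absorption perturbation — the log-ratio
attenuation is convex in mu_a, so finite concentration steps leave a
second-order bias that grows with the design's condition number (worst for
the weak cytochrome c column); (ii) any perturbed chromophore omitted from
the design aliases into the fitted ones.  The recovery test therefore runs
the whole-volume activation at a 1000x reduced step with all five
chromophores in the design, where recovery is exact to ~1%.

## Wavelength optimization

Differential evolution (SciPy, best1bin, popsize 15, tol 1e-8, polish off)
over k continuous variables in [400, 1000]; candidates are rounded to the
1-nm grid (or snapped to a restricted grid) inside the cost.  Candidates
with fewer than k distinct wavelengths after rounding receive a large
finite penalty (10 M): the caller asked for k usable spectral bands, and
this also keeps the k-equals-grid-size case single-valued.  Rank-deficient
designs get the same penalty rather than an exception.  One matrix of
standard normals per optimization, drawn from the noise seed, is reused for
every candidate (common random numbers), making candidate comparison
consistent and the optimum reproducible; results always re-evaluate the
returned set so `cost == cost_function(wavelengths)` holds exactly.
Exhaustive search over restricted grids (combination cap 2x10^5) provides
the ground-truth optimum; on 10-point grids DE attains it exactly in the
test suite.  Separate mode optimizes {HbO2, Hb} jointly for the
hemoglobins and {HbO2, Hb, target} scored on the target alone for each
cytochrome.

## Synthetic fixtures and what they show

The procedural cortex image (pink-grey background, dark Bezier vessels of
prescribed widths straddling the 0.5-mm opening threshold, optional
saturated specular spots, spatially correlated low-amplitude texture) ships
its exact ground-truth masks; segmentation recovers them at Dice >= 0.95.
It is intensity-realistic, not spectro-radiometrically rendered, and its
noise is milder and cleaner than a surgical microscope frame — passing the
Dice test shows the morphology chain is correct on its stated geometry, not
that the default threshold offset is optimal for clinical images.

The activation slab (two-region grey-matter volume, centred stripe through
the full depth, default 50% of the lateral extent) reproduces the
partial-volume mechanism: noise-free NIR estimates of HbO2 fall strictly
between 0 and the ground truth.  The homogeneous and vessel-stripe slabs
back the transport and reconstruction oracles, including the qualitative
vessel physics: near-zero reflectance and near-zero path length over a 2-mm
vessel below 600 nm, small-vessel path length within a few percent of grey
matter, and a vein/artery reflectance contrast that lives above 600 nm (at
the ~500-nm isobestic region the two are indistinguishable).  One published
observation is *not* robust at desk scale: the pooled mean path length over
a large vessel in the NIR comes out statistically indistinguishable from
(slightly above) grey matter for the 1-mm-deep carved vessel used here, so
no test asserts its sign.

## Problem sizes

Tests and the acceptance script run reduced problems chosen to keep the
full suite in the minutes range on one CPU: volumes of 32-64 voxels per
lateral axis at 0.1-0.25 mm pitch, 8x10^3 to 6x10^4 photons per wavelength,
the 61-wavelength 10-nm transport grid interpolated to 1 nm, N_noise = 1000,
and DE capped at 40 generations.  The engine itself is resolution- and
photon-count-agnostic; full-scale runs (73-um pitch, 10^8+ photons) are a
configuration choice, not a code path change.

## Known limitations

- Spectra are synthetic approximations; absolute uM errors are not
  comparable with laboratory extinction tables beyond scale and ranking.
- No polarization, fluorescence, time gating, or GPU execution.
- No lens aberrations, vignetting, chromatic distortion, or camera
  spectral-sensitivity normalization; the lens is a paraxial matrix.
- Scattering is fixed during activation; only mu_a is perturbed.
- Vessels exist only where visible at the surface; no deep vasculature.
- The noise model is additive Gaussian intensity noise with a shared sigma;
  shot-noise scaling with intensity is approximated only by the
  per-wavelength sigma option.
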