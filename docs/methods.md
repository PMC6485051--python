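# Methods

`portalqa` implements a portal-image quality-assessment pipeline — square-wave
MTF, contrast-detail scoring and 1-D gamma comparison — driven by a synthetic
generator that emulates the measurement conditions of a low-Z-target imaging
study: a 6 MeV electron beam on an external 8 mm aluminum target with a
polystyrene electron filter, imaged against a conventional 6 MV photon beam on
a computed-radiography (CR) detector.

## Beam model

Each beam mode is a binned photon-fluence spectrum on a 1 keV grid from 1 keV
to 6 MeV (so the 25/150 keV diagnostic-window boundaries fall exactly on bin
edges and window fractions are exact overlap sums).

* `al_target`: a Kramers thin-target shape `(Emax − E)/E` multiplied by a
  low-energy self-absorption rolloff `exp(−(28 keV/E)³)`. The rolloff constant
  is calibrated once so that 34.2% of the photon fluence lies in the
  25–150 keV window, the regime reported for aluminum-target beams; nothing
  else about the shape is asserted.
* `6mv`: a hardened megavoltage shape `(E/700 keV)² · exp(−E/700 keV)` with a
  negligible (0.14%) diagnostic-window share.

The unfiltered aluminum-target beam is bookkept as 64.2% photons / 35.8%
transmitted primary electrons per incident history. The polystyrene filter
acts on the two components separately:

* photons: Beer–Lambert per bin, no scatter buildup. The default polystyrene
  coefficient is a *constant* 0.0105/mm (Compton-dominated toy value). An
  energy-dependent coefficient would harden the spectrum and shift the
  diagnostic-window share of the transmitted photons by several percentage
  points over a 0–20 mm sweep, whereas the behaviour being modelled is a
  near-constant window share while electrons are removed; the flat
  coefficient makes that exact.
* electrons: survival `exp(−5 (t/R)²)` with `R` the CSDA range (default
  20 mm). This is a parametric stand-in, not transport physics: it is smooth,
  monotone, equals 1 at zero thickness and falls below 1% at the CSDA range.

`ParticleMix.low_energy_photon_fraction` is the 25–150 keV share **among
transmitted photons** (not among all particles): that is the quantity that
stays put as the filter removes electrons, and it is what the sweep's
stability property refers to.

Other materials (aluminum, brass, acrylic, water) use a two-term
photoelectric-plus-Compton parameterization
`μ(E) = pe₁₀₀ (100/E)³ + c₁₀₀ (100/E)^0.4` (1/mm, E in keV) with constants set
from each material's approximate attenuation at 100 keV and 2 MeV. Adequate
for ordering beams and materials between 25 keV and 6 MeV; not dosimetric
data.

## Phantom

The phantom carries the published element tables: 11 distinct bar-pattern
frequencies (equal bar/gap widths 4 … 0.15 mm, `f = 1/(2w)` lp/mm, stored at
full precision and compared to printed values at the printed digit count) and
27 circular low-contrast elements combining six diameters (15 … 1.1 mm) and
five thicknesses (0.5 … 4.8 mm).

Two deliberately synthetic choices, because the vendor layout is not
published:

* **Layout.** Bar blocks sit in two rows (4 periods per block, 13 mm bars);
  the low-contrast elements sit on a diameter-column × thickness-row grid at
  26 mm pitch, which keeps every element's background annulus clear of its
  neighbours. A 14-block variant duplicates the three lowest frequencies in
  diagonal orientation (the physical phantom has 14 lamella sets at 11
  frequencies; which three repeat, and how, is not published — neither
  variant is asserted as the vendor's truth).
* **Contrast-element sign.** The contrast-difference model
  `|E − E₀|/E₀ = 1 − e^(−Δμ t)` presumes the measurement area attenuates
  *more* than its background. The synthetic phantom therefore models the
  elements as aluminum discs of thickness `t` added over the base slab
  (measurement area darker), so the measured quantity obeys the model exactly
  rather than its `e^(Δμt) − 1` mirror image.

Geometry defaults: 95.2 cm SSD, 110 cm SID (magnification 1.1555…),
26 × 26 cm² field at the phantom plane. Coordinates are phantom-plane mm,
origin at the phantom centre, x rightward, y toward the gantry; images are
row-major, 0-based, +y mapping to decreasing row.

## Image formation

The renderer computes, per pixel, the line integral `τ = Σ μ̄ₘ tₘ` through
base slab, brass bars and aluminum discs, at phantom-plane coordinates scaled
by the projection magnification; the signal is `gain · e^(−τ)`, blurred with a
Gaussian PSF, noised and quantized to 16 bits.

**Effective-μ image formation.** Each material contributes with the
monoenergetic-equivalent coefficient `μ̄ = ⟨μ(E)⟩` averaged over the beam
spectrum, rather than the spectrum-weighted transmission `⟨e^(−μ(E)t)⟩`. The
two differ by beam-hardening terms (~8% of the contrast for the soft beam at
the deepest element); using μ̄ makes the renderer's hole contrast equal
`1 − e^(−μ̄ t)` exactly, i.e. the synthetic data obey the contrast-difference
law the analysis is built on, and parameter recovery is testable to 1%.
The beam dependence survives: the soft beam sees μ̄(aluminum) ≈ 0.050/mm vs
0.013/mm for the 6 MV beam, which is what drives its better contrast-detail
score.

**Detector.** The CR plate is modelled as a 2828 × 2320 canvas at 0.15 mm
pitch (pitch is not published for the reader used; 0.15 mm matches a 43 cm
plate at that pixel count). The energy dependence of the real detector
response is folded into two per-mode parameters rather than an
absorbed-energy model: PSF σ = 0.3 mm (al_target) vs 0.5 mm (6mv) at the
imager plane — chosen once so the synthetic critical frequencies fall in the
regime such systems report (~0.7 vs ~0.45 lp/mm) — and a common gain of
30000 counts at unit transmission. Noise is scaled-Poisson
(`Poisson(I/4)·4`, i.e. quantum noise with variance 4·I) plus Gaussian read
noise (σ = 30 counts), from one seeded generator per render; identical
inputs and seed give bit-identical images. Renders default to point sampling
at pixel centres (noiseless bar/hole regions stay exactly two-level);
`supersample > 1` switches to pixel-aperture integration on a finer grid.

Images are written non-inverted; display inversion is a metadata flag only
and is never applied before analysis.

What the generator does **not** emulate: CR phosphor physics and reader
optics, scatter and buildup, off-axis beam softening, detector glare/lag,
non-Gaussian PSF tails. Consequently passing tests demonstrate the
*analysis machinery* (contrast extraction, frequency interpolation,
classification, gamma) and the qualitative beam-quality ordering — they do
not certify agreement with any specific physical detector's f50/f10 or bar
visibility, which depend on hardware unavailable here.

## Spatial-resolution analysis

Per block, the bar-axis profile is the transverse mean of the block ROI
(2.5 mm inset from the bar ends). Contrast is `k = (max − min)/(max + min)`
with max/min read as the average of per-period peak maxima and trough minima
over interior periods — a robust reading of the max/min definition, since a
raw global max/min is noise-inflated. Numerical details that matter:

* the profile is cubic-spline upsampled ×16 before extrema are taken (raw
  pixel sampling can understate a near-sinusoidal modulation by >10% at
  4 px/period) and clipped to the sampled range (so hard two-level patterns
  are not overshot and an undegraded image yields MTF ≡ 1 exactly);
* blocks whose projected period falls below 4 px are skipped and reported,
  not measured;
* with 4 periods per block, the first and last period are excluded
  (pattern-end bleed); with fewer, all full periods are used.

`MTF(f)` is the image k divided by the object k (the ideal two-level
transmission contrast of the same block — identical for all blocks, taken
from render metadata or supplied by the caller). The relative curve is
normalized at the lowest measured frequency; the square-wave contrast ratio
is used directly as "MTF", with no square-wave→sine conversion, and the test
suite's independent oracle is correspondingly the square-wave response of the
PSF computed by direct convolution (closed-form erf sums on a dense grid,
read with the same per-interior-period estimator — at high frequency × blur
the finite 4-period pattern's end bleed is part of the measured signal, so
the oracle must read the same finite pattern).

f50 (critical) and f10 (limiting) frequencies are the *first downward
crossing* of 0.5/0.1 on the relative curve, linearly interpolated between
bracketing measured frequencies; an exact sample hit returns that frequency.
Non-monotone (noisy) curves therefore resolve to the earliest crossing. If
the curve never falls below the level, the highest measured frequency is
returned flagged censored. All frequencies are phantom-plane lp/mm.

## Contrast-detail analysis

Per element: `E` is the mean signal over a concentric disc at 80% of the
projected diameter, `E₀` the mean over a concentric annulus from 120% to 160%
of the projected diameter (shapes are a design choice — only "background
areas around the measurement areas" is specified; concentric sampling is
unbiased under the renderer's symmetric PSF). The contrast difference
`|E − E₀|/E₀` is classified green (≥ 5%), yellow ([3%, 5%)), red (< 3%);
thresholds are configurable constants defaulting to those conventional
values, with both lower boundaries inclusive. No observer model is applied:
visibility is the threshold rule only.

## Gamma analysis

Depth-dose curves are normalized to their maximum (= 100), lateral profiles
to the central-axis value. The evaluated (modelled) curve is linearly
resampled to a 1 mm grid with endpoints preserved; gamma is minimized
exhaustively over that grid within ±3·DTA of each reference point, with the
dose tolerance taken as percent of the reference's **global** normalization
dose (global normalization is the common convention when unstated; both
curves are normalized to a global reference anyway). No sub-grid refinement
is applied; the test suite bounds the 1 mm discretization error against a
0.01 mm dense-grid oracle. Evaluation can be restricted to a position window
(in-field / open-beam region). Depth-dose agreement is additionally reported
as both the maximum and the mean pointwise deviation in percent of maximum,
since stated agreement levels in practice rarely say which was meant.

## Problem sizes and defaults used by the shipped analyses

The numbered analysis scripts and `scripts/acceptance.py` run the phantom
renders at the native 0.15 mm pitch on a canvas cropped to the phantom
footprint plus margin (≈1610 × 1615 px) rather than the full CR plate — the
phantom occupies a fraction of the plate and the analyses only consume
phantom ROIs. Dose-curve fixtures use 2 mm native sampling over 0–300 mm
(depth dose) and ±160 mm (profile). The synthetic modelled curves are
perturbed by 1.2% dose offset + 0.3% noise (depth dose) and 1 mm shift + 1%
output (profile) — representative commissioning-scale discrepancies that an
all-pass 3%/3 mm gamma should absorb.

## Known limitations

* The toy spectra and two-term attenuation curves are ordering-faithful, not
  dosimetric; absolute f50/f10 and visibility counts are properties of the
  synthetic detector defaults.
* A single Gaussian PSF cannot reproduce the long-tailed blur of real CR
  systems, whose limiting/critical frequency ratio is larger than a
  Gaussian's fixed f10/f50 ≈ 1.8; the soft beam's f10 can exceed the highest
  measurable frequency on the default canvas and is then reported censored.
* The gamma implementation is 1-D only, by design.
* Electron survival and filter behaviour are qualitative; no claim is made
  about absolute contaminant dose.
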