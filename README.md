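# portalqa

Quality analysis of radiotherapy portal images for low-Z-target imaging
beams: square-wave (bar-pattern) MTF with critical/limiting frequency
extraction, contrast-detail scoring, and 1-D gamma comparison of dose curves
— plus a synthetic phantom-image and beam-model generator that emulates the
measurement conditions.

## The problem

Portal images — images taken with the treatment beam itself to verify patient
positioning — are notoriously poor at megavoltage energies, where Compton
scattering flattens subject contrast. One remedy is to generate the imaging
beam on a thin low-Z target (here: 8 mm aluminum in the accessory tray of a
6 MeV electron mode, with a 20 mm polystyrene slab to stop transmitted
electrons), which enriches the beam in diagnostic-quality 25–150 keV photons.
Whether that actually buys image quality is a measurement question, answered
with a QC phantom and three standard tools:

* **Spatial resolution** from bar patterns of equal bar/gap width *w*
  (frequency *f* = 1/(2*w*) lp/mm). Per block, contrast is
  *k* = (max − min)/(max + min) of the bar profile, and

      MTF(f) = k_image(f) / k_object ,

  normalized to the lowest measured frequency. The **critical frequency
  f₅₀** (relative MTF = 0.5) quantifies sharpness; the **limiting frequency
  f₁₀** (relative MTF = 0.1) the resolution limit.
* **Contrast resolution** from 27 low-contrast elements spanning six
  diameters and five thicknesses *t*, scored by the contrast difference

      |E − E₀| / E₀ = 1 − e^(−Δμ·t) ,

  with E/E₀ the mean signal in the element / surrounding background, and
  classified ≥5% distinguishable (green), 3–5% barely (yellow), <3%
  indistinguishable (red).
* **Gamma index** γ at 3%/3 mm (evaluated curve resampled to 1 mm) for
  comparing modelled against measured depth-dose and lateral-profile curves;
  γ ≤ 1 everywhere means the dose model is acceptable.

Real CR images and Monte Carlo phase spaces are not reproducible at desk
scale, so the package ships a first-class synthetic generator (toy spectra,
effective-attenuation transmission imaging, beam-dependent Gaussian PSF,
Poisson + Gaussian noise) whose defaults emulate the study conditions; see
`docs/methods.md` for the model and its limits.

## Worked example

```
$ python analysis/01_optimize_electron_filter.py     # electron-filter sweep
$ python analysis/02_validate_dose_model.py          # gamma validation
$ python analysis/03_compare_image_quality.py        # the headline comparison

Shared seed 1, full-resolution phantom canvas (0.15 mm pixels).

al_target:
  f50 = 0.855 lp/mm, f10 = 1.429 lp/mm (censored)
  contrast-detail: 15 green / 5 yellow / 7 red
6mv:
  f50 = 0.485 lp/mm, f10 = 0.962 lp/mm
  contrast-detail: 2 green / 4 yellow / 21 red
```

Reading: on paired synthetic images with a common seed, the aluminum-target
beam's relative MTF stays above 50% out to 0.855 lp/mm versus 0.485 lp/mm for
the conventional 6 MV beam (its f₁₀ exceeds the highest measurable frequency
on this canvas, hence "censored"), and 15 of the 27 low-contrast elements are
distinguishable versus 2 — the soft photon component both sharpens bar
patterns and deepens element contrast. The filter sweep shows transmitted
electrons falling from 35.8% to 0.24% of incident histories at 20 mm
polystyrene while the 25–150 keV share of the photons stays at 34.2%; the
dose validation finds modelled depth dose within 0.88% of measured and all
gamma values below one at 3%/3 mm.

The same steps are available as a CLI for file-based workflows:

```
portalqa simulate --beam al_target --out al.tif --seed 1
portalqa mtf al.tif --out mtf.json
portalqa contrast al.tif --out cd.json
portalqa gamma measured.csv modelled.csv --normalize max --out gamma.json
portalqa report --seed 1 --out results/
```

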