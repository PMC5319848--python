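# sarcometrics

Quantitative sarcomere morphometry and titin isoform analysis for striated
muscle, with a fully seeded synthetic-data generator for validation by
parameter recovery.

Striated-muscle biologists characterise short-sarcomere phenotypes with a
small, standard toolkit: 1D fluorescence intensity profiles drawn along
myofibrils perpendicular to the striations, in which major peaks mark
alpha-actinin-positive Z-discs and minor peaks mark Tmod1-capped
thin-filament pointed ends; phalloidin banding geometry (a dark H band when
`SL > 2 TFL`, an extra bright band when thin filaments overlap past
mid-sarcomere); titin N2B/N2BA isoform ratios from two-band gel
densitometry or a qPCR element index; and Hill fits of force-pCa curves
from skinned fibres. `sarcometrics` implements that toolkit as a tested,
reusable library plus CLI:

- **simulate** — a forward optical model of immunostained myofibrils
  (phalloidin coverage counts, PSF-blurred epitope impulses, 2D rotated
  renderings), plus generators for TFL~SL populations, gel lanes, qPCR Ct
  tables, force-pCa curves and postnatal isoform-transition series, all
  from explicit ground truth with seeded reproducibility.
- **morphometry** — striation-orientation estimation from the 2D power
  spectrum, width-averaged profile extraction, prominence/separation peak
  detection with subpixel refinement, sarcomere length (SL, Z-to-Z) and
  thin-filament length (TFL, Z-to-pointed-end) measurement, FFT-based SL,
  banding phenotype classification and per-cell/population aggregation.
- **isoform** — gel-lane baseline subtraction and two-band Gaussian
  quantification (%N2B of total titin), 2^-ddCt fold changes, the
  N2A/N2B-element %N2B index (`fraction_N2BA = eff^-(Ct_N2A - Ct_N2B)`),
  and per-stage transition testing with Bonferroni correction.
- **stats** — TFL~SL OLS with ANCOVA-style slope/elevation/intercept
  comparison, normality/variance-gated two-group tests, per-segment
  variance profiling, the Hill force-pCa fit
  `F = f_max / (1 + 10^(n_H (pCa - pCa50)))`, and cardiac index arithmetic
  (SV = EDV - ESV, EF = 100 SV/EDV, CO = SV x HR, fWT).
- **pipeline / CLI** — YAML-configured scenarios (`sarcometrics run
  --preset wildtype-vs-knockout`) that simulate, measure, quantify and
  compare two genotypes end to end, with provenance sidecars and
  byte-reproducible outputs under a fixed seed.

## Worked example

```python
import sarcometrics as sm

# a myofibril of six 2.5 um sarcomeres with 1.02 um thin filaments
truth = sm.SarcomereGroundTruth.from_sl_tfl([2.5] * 6, [1.02] * 6, "demo")
optics = sm.OpticalModelParams(noise_sd=0.02)
profiles = sm.simulate_profile(
    truth, optics, ("alpha_actinin", "tmod1", "phalloidin"), rng=0)

cell = sm.measure_cell(profiles, "demo")
print(f"SL  = {cell.sl_mean:.3f} +/- {cell.sl_sd:.3f} um "
      f"({cell.n_sarcomeres} sarcomeres)")
print(f"TFL = {cell.tfl_mean:.3f} +/- {cell.tfl_sd:.3f} um "
      f"({cell.tfl_values.size} pointed ends)")
print(f"phenotype: {cell.phenotype}")
print(f"FFT cross-check SL = {sm.measure_sl_fft(profiles['alpha_actinin']):.3f} um")

curve = sm.simulate_force_pca(5.94, 2.0, 25.0, 2.0,
                              [7.0, 6.6, 6.4, 6.2, 6.1, 6.0,
                               5.9, 5.8, 5.6, 5.4, 5.0, 4.6],
                              noise_sd=0.2, rng=1)
fit = sm.fit_force_pca(curve)
print(f"pCa50 = {fit.pca50:.3f}, n_H = {fit.n_hill:.2f}, F_max = {fit.f_max:.1f}")
```

prints

```
SL  = 2.499 +/- 0.005 um (6 sarcomeres)
TFL = 1.019 +/- 0.004 um (12 pointed ends)
phenotype: h_band_visible
FFT cross-check SL = 2.501 um
pCa50 = 5.940, n_H = 2.00, F_max = 25.1
```

The generating SL (2.5), TFL (1.02) and pCa50 (5.94) are recovered to a
few nanometres / millipCa; `h_band_visible` is correct because
`SL - 2 TFL = 0.46 um` exceeds the 0.2 um resolution limit. The same chain
works from images: `sm.simulate_image` renders rotated multi-channel TIFF
stacks, `sm.estimate_orientation` finds the striation normal from the power
spectrum, and `sm.extract_profile` pulls the width-averaged trace.

From the shell:

```sh
sarcometrics run --preset wildtype-vs-knockout --out-dir out/
sarcometrics simulate out/bundle --sl-mean 1.81 --orientation-deg 37
sarcometrics measure out/bundle out/cells.csv
```

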