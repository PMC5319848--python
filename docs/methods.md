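# Methods

`sarcometrics` re-implements, as a tested pipeline, the quantitative
analyses used to characterise a short-sarcomere cardiac phenotype:
fluorescence-profile morphometry of sarcomere length (SL) and thin-filament
length (TFL), phalloidin-banding phenotype classification, titin N2B/N2BA
isoform quantification by gel densitometry and by a qPCR element index,
TFL~SL regression comparison between genotypes, and Hill fitting of
force-pCa curves. Because the underlying measurements were made on animal
tissue, validation is by **parameter recovery**: a synthetic-data module
generates every input from explicit ground truth, the measurement pipeline
runs blind, and the recovered estimates are compared with the generating
values.

## Forward optical model

A myofibril is a strictly increasing sequence of Z-disc positions with one
thin-filament length per sarcomere. Thin filaments span `[z, z+TFL]` to the
right and `[z-TFL, z]` to the left of each Z-disc, so phalloidin intensity
is the filament *coverage count* (0/1/2) scaled by a thin-filament
amplitude, plus a Gaussian boost at each Z line. This reproduces the two
banding phenotypes that matter: a dark H band of width `SL - 2 TFL` when
thin filaments do not meet, and a double-intensity overlap band of width
`2 TFL - SL` when they interdigitate. Alpha-actinin (Z), myomesin (M),
Tmod1 (pointed ends at `z ± TFL`) and titin epitopes are unit-height
Gaussian impulses. Everything is convolved with a Gaussian PSF analytically
(boxcars via the error function), offset by a baseline and degraded with
additive Gaussian noise. Additive (rather than Poisson) noise is a
deliberate simplification: fixed-tissue confocal imaging of bright
immunostains is high-SNR, and the additive model keeps every oracle in the
test suite analytic.

Key optical defaults: pixel size 0.05 um, PSF sigma 0.10 um (typical
confocal lateral resolution for ~1 um banding), per-pixel noise SD 0.05
(SNR ~20 against the Z-line amplitude). Directly rendered 1D traces use
noise SD 0.02 instead: a drawn line profile averages ~8 parallel pixel
rows, so the trace-level noise of per-pixel imaging is reduced by about
sqrt(8). Titin-epitope and regression measurements use PSF sigma 0.05,
emulating a structured-illumination system; this matters because twin Tmod1
or exon-epitope bands can sit 0.2-0.3 um apart, unresolvable at confocal
width (the unresolvable case is itself exercised and flagged).

Titin epitope placement is linear in SL: `offset = c + s (SL - 2.0)` um
from the Z-disc per flank, with defaults c49 = 0.10, s49 = 0.05 for exon 49
and c224 = 0.25, s224 = 0.15 for exon 224. No quantitative epitope-to-Z
distances are available for these epitopes, so these coefficients are
placeholders chosen to be geometrically plausible; the slope is halved for
N2B-dominant fibrils (the N2B spring region barely extends) and scaled by
0.75 for mixed populations, an interpolation of our own.

## Population generator

Per cell, a cell-level mean SL is drawn `Normal(sl_mean, cell_sl_sd)`; per
sarcomere, `Normal(cell_mean, sl_sd)` truncated above 0.8 um (below the
physical myofilament minimum; the shortest length seen in tissue is
~1.18 um). TFL follows `tfl_slope * SL + tfl_intercept + Normal(0,
tfl_noise_sd)` truncated into `(0, SL)`; a population spec whose TFL law violates
`TFL < SL` in over half the draws is rejected as degenerate. The
`cell_sl_sd` field exists because isolated-cell experiments report box
plots of *cell means*: per-sarcomere draws alone cannot reproduce a
between-cell IQR. All sampling flows through explicit
`numpy.random.Generator` seeds; nothing touches global state.

### Preset study conditions

The presets encode one experimental arm each (values in um unless noted):

| condition | +/Y | -/Y |
|---|---|---|
| section SL (per sarcomere) | 1.81 ± 0.09 | 1.52 ± 0.21 |
| isolated-cell SL (cell means) | 1.75, IQR width 0.05 | 1.68, IQR width 0.15 |
| TFL | 1.06 ± 0.05 | 0.98 ± 0.09 |
| TFL~SL law | 0.35·SL + 0.21 | 0.27·SL + 0.38 |
| gel %N2B | 90.5 | 92.9 |
| qPCR %N2B | 82.4 | 93.7 |
| pCa50 | 5.94 | 5.92 |

Between-cell SDs for the isolated-cell presets come from the IQR widths
under normality (IQR/1.349). Two rendering choices deserve emphasis.
First, the reported adult TFL means (≈1 um) exceed half the diastolic
section SL (≈1.5-1.8 um); in a symmetric sarcomere a pointed end beyond
mid-sarcomere is indistinguishable from one at `SL - TFL`, so Z-to-Tmod1
distances are only measurable when `TFL < SL/2`. The TFL and regression
presets therefore render myofibrils at stretched SL (2.6-2.8 um mean) —
the TFL distributions and regression laws are the ground truth being
recovered; the fibril SL there is a rendering condition, not a target.
Second, regression points aggregate the two flanks of a sarcomere into one
observation: the generator gives both flanks the same TFL draw, and
treating them as independent points would pseudo-replicate the regression
and understate its standard errors.

The postnatal transition presets give both genotypes a common %N2B
trajectory through P1, with the knockout precociously elevated from P5
onward and both arms ending at the adult qPCR values; the intermediate
stage values are plausible interpolations (the source reports them only
graphically).

## Measurement pipeline

**Orientation.** The striation normal is the direction of the dominant
off-centre peak of the 2D power spectrum, refined by a 3x3
intensity-weighted centroid (sub-degree accuracy for a dozen periods).
Periods longer than 4.5 um are masked around DC so the banded region's
envelope cannot win; a peak below 50x the median off-centre power raises
"no striations detected" (white noise tops out near 35x for megapixel
images).

**Profile extraction.** Line profiles are bilinear samples along the
striation normal, averaged over parallel offset lines (default 8 px). For
diagonal lines the recorded spacing is the Euclidean step, not one pixel.

**Peak detection.** Local maxima with topographic prominence at least
`prominence_frac` (default 0.2) of the dynamic range, separated by at least
`min_separation_um` (default 0.8 um — below the physiological minimum SL;
taller peaks win ties). Positions are refined by a 3-point parabola, exact
for locally quadratic peaks and clipped to half a sample. The same rules
are reimplemented naively (exhaustive scans) in the test suite and the two
implementations are required to agree on a thousand random profiles.
Channels carrying sub-SL structure (Tmod1, titin epitopes) use smaller
separations (0.15-0.3 um).

**SL and TFL.** SL is the consecutive Z-peak spacing, guarded to
[0.8, 4.0] um against spurious peaks (discards are logged). Per-cell SL is
the unweighted mean of spacings, and population statistics are computed
over cell means, not pooled sarcomeres. TFL pairs each pointed-end peak
with its nearest Z (ties to the left Z, deterministically), kept only when
the distance is under half the local SL. An FFT estimator (Hann window,
4x zero-padding, lowest strong in-band spectral peak as the fundamental,
parabolic bin refinement) cross-checks the peak-based SL to within 2%.

**Phenotype.** `classify_phenotype(sl, tfl)` applies the band geometry
directly: H band visible when `SL - 2 TFL` exceeds the 0.2 um resolution
limit, overlap band when `2 TFL - SL` exceeds it, otherwise unresolved.
Because pointed-end distances cannot see overlap (above), the per-cell
pipeline classifies from the phalloidin trace itself: for each sarcomere
the mid-sarcomere window is compared against the single-coverage I-band
plateau (sampled 0.25-0.4 SL from each Z, clear of the Z boost); a central
dip or excess of at least half the coverage step votes H band or overlap,
and the cell takes the majority vote.

**Gel densitometry.** A linear baseline anchored at the minima flanking
the band region is subtracted and negative residuals clipped. The two most
prominent bands are fit as Gaussians plus a constant floor (the floor
absorbs the positive-mean residual that clipping leaves in band-free
stretches; without it the weak band's width inflates by ~2% N2BA at lane
SNR ~19). Band identity is by migration order alone — the smaller N2B
isoform migrates farther — and %N2B is the analytic area fraction, so %N2B
and %N2BA sum to 100 exactly and the result is invariant to lane-wide
scaling. Merged bands yield a censored result, not a number.

**qPCR.** Replicates average on the Ct scale. Fold changes use 2^-ddCt
against a reference gene and control group. The %N2B index assumes the
transcript-mixture model — every titin transcript carries the N2B element,
only N2BA transcripts the N2A element — giving `fraction_N2BA =
efficiency^-(Ct_N2A - Ct_N2B)` with efficiency fixed at 2.0 by default.
The index is exact under its model but should be read as a *relative*
tracker of the N2BA-to-N2B transition: it inherits the model's assumptions,
not a standard curve. `Ct_N2A < Ct_N2B` beyond a 0.5-cycle noise floor is
a model violation, clipped to 0% with a warning; a censored N2A Ct maps to
100% N2B.

**Statistics.** Two-group tests gate on Shapiro-Wilk normality (both
groups) and a two-sided F-test of variances, each at alpha 0.05: Student's
t when all gates pass, Mann-Whitney otherwise, two-sided throughout; gate
decisions travel with the result, and the gated procedure's type-I error
is verified to sit in [0.03, 0.07] at nominal 0.05. Regression comparison
is classical ANCOVA: slope equality via the interaction term of the pooled
model, elevation (common-slope offset) conditional on slope equality,
intercepts from the full model. Bonferroni is the only multiplicity
correction; the transition analysis uses the number of tested stages as
the family size. The force-pCa fit subtracts passive force, then fits
`F = f_max / (1 + 10^(n_H (pCa - pCa50)))` by nonlinear least squares from
(6.0, 2.0, max(active)); the Hill form is the field-standard model for
Ca2+ sensitivity and n_H defaults to 2.0 in the generator (typical cardiac
range 2-4). A grid-search oracle over (pCa50, n_H) with analytic f_max
verifies the fit's RSS is never beaten.

## Recovery experiments and problem sizes

`sarcometrics.recovery` (driven by `scripts/acceptance.py`) re-runs each
arm end to end. Section SL uses 72 cells x 12 sarcomeres rendered as 2D
two-channel images at random orientations, measured via orientation
estimation, extraction and peak detection. Isolated-cell SL uses the
study's cohort sizes (55 and 63 cells); because the knockout between-cell
SD (~0.11) puts a single cohort's grand-mean SE near 0.018, the experiment
averages six independent cohorts — replication reduces the validator's
Monte-Carlo noise without altering the per-cohort study conditions. TFL
and regression use 60 fibrils x 10 sarcomeres; the study-scale
significance check redraws 10 fibrils x 3 sarcomeres (~30 regression
points per group, residual SD 0.09), where both slopes are reliably
non-zero but a 0.08 slope difference is not resolvable — the expected
testing behaviour at that sample size (about one seed in ten will
nonetheless call the difference significant; that is the statistics, not a
defect). qPCR and gel recoveries use noiseless tables/lanes for the exact
checks and 0.2-cycle / 0.5-OD noise for the noisy ones.

## What the synthetic data does and does not show

The generator emulates banding geometry, channel registration, PSF blur,
additive noise, isoform-dependent epitope placement, Ct arithmetic with
technical jitter, two-band lanes with linear baselines, and Hill-shaped
activation. It does **not** emulate: myofibril curvature or crossing,
out-of-plane tilt (a real confounder the isolated-cell experiments exist
to avoid), asymmetric sarcomeres (flanks share one TFL), Poisson/photon
noise, bleaching or saturation, gel smiling or lane-to-lane distortion,
amplification-efficiency drift between targets, or the nested
variance structure of sarcomeres within cells within hearts (no
mixed-effects modelling — the original analyses did not use one either,
and this is a known limitation). Passing recovery therefore demonstrates
that the measurement chain is unbiased and correctly calibrated under the
stated optical model, not that it is robust to every artefact of real
micrographs.

## Numerical notes and degenerate inputs

Parabolic refinements are clipped to half a bin/sample and skip edge
peaks; two-means peak splitting initialises deterministically at the
min/max height and errors when the split means are closer than 10% of the
height range; fibrils shorter than 3 sarcomeres are rejected at
simulation; empty peak sets and pairless TFL calls return flagged empty
results rather than raising; `pCa` grids that do not bracket the fitted
midpoint warn about extrapolation; identical samples compare with p = 1.
Determinism: identical spec + seed gives bit-identical profiles, images,
populations and scenario CSVs (verified in tests).
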