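"""Canonical study conditions for the wild-type (+/Y) vs knockout (-/Y)
comparison, expressed as generator specs.

Each preset encodes the generating distribution of one experimental arm:
diastole-fixed section imaging, isolated-cell imaging, dual-channel
thin-filament measurement, TFL~SL regression populations, gel and qPCR
isoform assays, force-pCa curves and the postnatal transition series.
These values parameterise the synthetic-data module so that the measurement
pipeline can be validated by parameter recovery.
"""

from __future__ import annotations

from .simulate import OpticalModelParams, PopulationSpec, QpcrTruth

__all__ = [
    "DEFAULT_OPTICS",
    "PROFILE_OPTICS",
    "SIM_OPTICS",
    "SECTION_POPULATIONS",
    "ISOLATED_CELL_POPULATIONS",
    "TFL_POPULATIONS",
    "REGRESSION_POPULATIONS",
    "REGRESSION_OPTICS",
    "GEL_PCT_N2B",
    "QPCR_TRUTHS",
    "FORCE_PCA",
    "TRANSITION_STAGES",
    "TRANSITION_PCTS",
]

#: Confocal-like optics: 0.05 um pixels, 0.10 um PSF sigma, modest additive
#: per-pixel noise (SNR ~ 20 against the Z-line amplitude). Use for 2D
#: image rendering.
DEFAULT_OPTICS = OpticalModelParams(noise_sd=0.05)

#: Optics for directly rendered 1D traces. A drawn line profile averages
#: ~8 parallel pixel rows, so the trace-level noise of 0.05-per-pixel
#: imaging is about 0.05/sqrt(8) ~ 0.02.
PROFILE_OPTICS = OpticalModelParams(noise_sd=0.02)

#: Structured-illumination-like optics used for titin epitope imaging,
#: where ~0.2 um band pairs must be resolved.
SIM_OPTICS = OpticalModelParams(psf_sigma=0.05, noise_sd=0.02)

#: Diastole-fixed left-ventricular sections: per-sarcomere SL distributions.
#: The knockout arm is both shorter and far more variable.
SECTION_POPULATIONS = {
    "+/Y": PopulationSpec(n_cells=72, n_sarcomeres=12, sl_mean=1.81,
                          sl_sd=0.09, tfl_slope=0.35, tfl_intercept=0.21,
                          tfl_noise_sd=0.03),
    "-/Y": PopulationSpec(n_cells=72, n_sarcomeres=12, sl_mean=1.52,
                          sl_sd=0.21, tfl_slope=0.27, tfl_intercept=0.38,
                          tfl_noise_sd=0.05),
}

#: Isolated fixed cardiomyocytes (myomesin striations). Here the interesting
#: spread is BETWEEN cell means (the box-plot populations): the knockout IQR
#: of cell means is three times wider (0.15 vs 0.05 um), giving between-cell
#: SDs of 0.15/1.349 and 0.05/1.349 under normality.
ISOLATED_CELL_POPULATIONS = {
    "+/Y": PopulationSpec(n_cells=55, n_sarcomeres=12, sl_mean=1.75,
                          sl_sd=0.04, cell_sl_sd=0.05 / 1.349,
                          tfl_slope=0.35, tfl_intercept=0.21,
                          tfl_noise_sd=0.03),
    "-/Y": PopulationSpec(n_cells=63, n_sarcomeres=12, sl_mean=1.68,
                          sl_sd=0.06, cell_sl_sd=0.15 / 1.349,
                          tfl_slope=0.27, tfl_intercept=0.38,
                          tfl_noise_sd=0.05),
}

#: Dual-channel (alpha-actinin / Tmod1) thin-filament measurement. The TFL
#: distributions are the recovery targets; the myofibrils are rendered at a
#: stretched SL (2.6 um) so that pointed ends stay short of mid-sarcomere
#: (TFL < SL/2) and Tmod1 bands are optically separable, the regime in which
#: Z-to-pointed-end profiles give well-defined minor peaks.
TFL_POPULATIONS = {
    "+/Y": PopulationSpec(n_cells=60, n_sarcomeres=10, sl_mean=2.6,
                          sl_sd=0.08, tfl_slope=0.0, tfl_intercept=1.06,
                          tfl_noise_sd=0.05),
    "-/Y": PopulationSpec(n_cells=60, n_sarcomeres=10, sl_mean=2.6,
                          sl_sd=0.08, tfl_slope=0.0, tfl_intercept=0.98,
                          tfl_noise_sd=0.09),
}

#: TFL~SL regression populations: the printed per-genotype linear laws with
#: scatter. SL is spread widely (for slope leverage) and kept high enough
#: that the TFL law stays below SL/2 in essentially all draws and the twin
#: Tmod1 bands (SL - 2 TFL apart) remain optically separable.
REGRESSION_POPULATIONS = {
    "+/Y": PopulationSpec(n_cells=60, n_sarcomeres=10, sl_mean=2.6,
                          sl_sd=0.18, tfl_slope=0.35, tfl_intercept=0.21,
                          tfl_noise_sd=0.05),
    "-/Y": PopulationSpec(n_cells=60, n_sarcomeres=10, sl_mean=2.8,
                          sl_sd=0.25, tfl_slope=0.27, tfl_intercept=0.38,
                          tfl_noise_sd=0.08),
}

#: Optics for the regression measurements: structured-illumination-like PSF
#: so that the +/Y Tmod1 twin bands (down to ~0.2 um apart at the low-SL end
#: of the regression window) resolve without positional pull.
REGRESSION_OPTICS = OpticalModelParams(psf_sigma=0.05, noise_sd=0.02)

#: Gel densitometry %N2B group means.
GEL_PCT_N2B = {"+/Y": 90.5, "-/Y": 92.9}

#: Adult ventricle qPCR isoform fractions.
QPCR_TRUTHS = {
    "+/Y": QpcrTruth(pct_n2b=82.4, tech_noise_sd=0.2),
    "-/Y": QpcrTruth(pct_n2b=93.7, tech_noise_sd=0.2),
}

#: Skinned-trabecula Ca2+ sensitivity: pCa50 per genotype; the Hill
#: coefficient is not constrained by the study, 2.0 is field-typical.
FORCE_PCA = {
    "+/Y": {"pca50": 5.94, "n_hill": 2.0, "f_max": 25.0, "passive_force": 2.0},
    "-/Y": {"pca50": 5.92, "n_hill": 2.0, "f_max": 25.0, "passive_force": 2.0},
}

#: Postnatal titin isoform transition: %N2B trajectories per genotype. Both
#: genotypes run together through P1; the knockout up-regulates N2B
#: precociously from P5 and both arms end at the adult qPCR values.
TRANSITION_STAGES = ["E14.5", "E16.5", "E18.5", "P1", "P5", "P10", "P21",
                     "adult"]
TRANSITION_PCTS = {
    "+/Y": [2.0, 4.0, 8.0, 20.0, 40.0, 60.0, 80.0, 82.4],
    "-/Y": [2.0, 4.0, 8.0, 20.0, 55.0, 75.0, 90.0, 93.7],
}
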