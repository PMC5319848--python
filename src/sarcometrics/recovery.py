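"""Parameter-recovery experiments: seed the simulator with a study arm's
generating parameters, run the measurement pipeline blind, and report the
recovered quantity.

These are the package's end-to-end validation runs. Each function draws a
synthetic cohort under one of the preset study conditions
(:mod:`sarcometrics.presets`), pushes it through the same code paths a user
would apply to real data (image rendering -> orientation estimation ->
profile extraction -> peak detection -> measurement -> statistics), and
returns the recovered estimate together with the cohort size.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import morphometry as mm
from . import presets, simulate, stats
from .isoform import pct_n2b_from_ct, quantify_lane, subtract_baseline

__all__ = [
    "recover_section_sl",
    "recover_isolated_cell_sl",
    "recover_tfl",
    "recover_regression_slope",
    "regression_significance",
    "recover_qpcr_pct",
    "recover_gel_pct",
    "recover_pca50",
]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def recover_section_sl(group: str, seed=0, n_cells: int | None = None,
                       ) -> tuple[float, int]:
    """Grand mean SL from synthetic diastole-fixed section images.

    Each cell is rendered as a 2D two-channel (phalloidin / alpha-actinin)
    image at a random striation orientation; the pipeline estimates the
    orientation from the power spectrum, extracts a width-averaged line
    profile along the striation normal, detects alpha-actinin peaks and
    measures Z-to-Z spacings. Returns (mean of cell means, n cells).
    """
    spec = presets.SECTION_POPULATIONS[group]
    if n_cells is not None:
        spec = replace(spec, n_cells=n_cells)
    rng = _rng(seed)
    optics = presets.DEFAULT_OPTICS
    extent_um = spec.n_sarcomeres * (spec.sl_mean + 3.5 * spec.sl_sd) + 4.0
    size_px = int(np.ceil(extent_um / optics.pixel_size))
    cell_means = []
    for truth in simulate.simulate_population(spec, rng=rng):
        orientation = float(rng.uniform(0.0, 180.0))
        image, _ = simulate.simulate_image(
            [truth], optics, orientation, size_px, rng=rng,
            channels=("alpha_actinin", "phalloidin"))
        angle = mm.estimate_orientation(image[0], pixel_size=optics.pixel_size)
        profile = mm.extract_profile(image[0], angle_deg=angle,
                                     pixel_size=optics.pixel_size,
                                     averaging_width_px=8,
                                     channel="alpha_actinin")
        sl = mm.measure_sl(mm.detect_peaks(profile))
        if sl.size:
            cell_means.append(float(np.mean(sl)))
    return float(np.mean(cell_means)), len(cell_means)


def recover_isolated_cell_sl(group: str, seed=0,
                             n_replicates: int = 6) -> tuple[float, int]:
    """Mean of per-cell SL from isolated-cardiomyocyte myomesin profiles.

    Striation traces are rendered per cell (myomesin M-line channel), peaks
    are detected and the per-cell SL is the mean peak spacing; the
    population statistic is the mean of cell means. Because the knockout
    arm's between-cell spread is wide relative to its cohort size, the
    experiment is replicated ``n_replicates`` times at the study's n and the
    cohort means are averaged, keeping cohort-sampling noise below the
    measurement scale. The returned n is the per-cohort cell count.
    """
    spec = presets.ISOLATED_CELL_POPULATIONS[group]
    rng = _rng(seed)
    optics = presets.PROFILE_OPTICS
    cohort_means = []
    for _ in range(n_replicates):
        cell_means = []
        for truth in simulate.simulate_population(spec, rng=rng):
            profs = simulate.simulate_profile(truth, optics, ("myomesin",),
                                              rng=rng)
            sl = mm.measure_sl(mm.detect_peaks(profs["myomesin"]))
            if sl.size:
                cell_means.append(float(np.mean(sl)))
        cohort_means.append(float(np.mean(cell_means)))
    return float(np.mean(cohort_means)), spec.n_cells


def recover_tfl(group: str, seed=0) -> tuple[float, int]:
    """Mean TFL from dual-channel (alpha-actinin / Tmod1) myofibril profiles.

    Pointed ends pair to their nearest Z-disc under the half-local-SL guard;
    the reported value is the mean of per-fibril TFL means.
    """
    spec = presets.TFL_POPULATIONS[group]
    rng = _rng(seed)
    optics = presets.PROFILE_OPTICS
    fibril_means = []
    for truth in simulate.simulate_population(spec, rng=rng):
        profs = simulate.simulate_profile(
            truth, optics, ("alpha_actinin", "tmod1"), rng=rng)
        z = mm.detect_peaks(profs["alpha_actinin"])
        t = mm.detect_peaks(profs["tmod1"], min_separation_um=0.3)
        tfl = mm.measure_tfl(z, t)
        if tfl.size:
            fibril_means.append(float(np.mean(tfl)))
    return float(np.mean(fibril_means)), len(fibril_means)


def _measured_pairs(spec: simulate.PopulationSpec, rng: np.random.Generator):
    """(local SL, TFL) regression points measured through the dual-channel
    pipeline, imaged at structured-illumination resolution so closely spaced
    twin Tmod1 bands at the short-SL end resolve cleanly.

    The two flanks of a sarcomere are averaged into one point: under the
    symmetric forward model they probe the same thin-filament length, and
    treating them as two observations would pseudo-replicate the regression.
    """
    optics = presets.REGRESSION_OPTICS
    sl_all, tfl_all = [], []
    for truth in simulate.simulate_population(spec, rng=rng):
        profs = simulate.simulate_profile(
            truth, optics, ("alpha_actinin", "tmod1"), rng=rng)
        z = mm.detect_peaks(profs["alpha_actinin"])
        t = mm.detect_peaks(profs["tmod1"], min_separation_um=0.15)
        pairs = mm.measure_tfl_pairs(z, t)
        if pairs.empty:
            continue
        # sarcomere index: a right-flank filament belongs to the sarcomere
        # right of its Z, a left-flank filament to the one left of it
        sarc = pairs["z_index"] - (pairs["flank"] == "left").astype(int)
        per_sarc = pairs.assign(sarc=sarc).groupby("sarc").agg(
            tfl_um=("tfl_um", "mean"), local_sl_um=("local_sl_um", "first"))
        sl_all.extend(per_sarc["local_sl_um"])
        tfl_all.extend(per_sarc["tfl_um"])
    return np.asarray(sl_all), np.asarray(tfl_all)


def recover_regression_slope(group: str, seed=0) -> tuple[float, int]:
    """OLS slope of the TFL-vs-SL relation measured through the pipeline."""
    x, y = _measured_pairs(presets.REGRESSION_POPULATIONS[group], _rng(seed))
    fit = stats.fit_linear(x, y, group)
    return fit.slope, fit.n


def regression_significance(seed=0, n_fibrils: int = 10,
                            n_sarcomeres: int = 3) -> dict:
    """Regression testing behaviour at study-scale sample size.

    Both genotype populations are re-drawn at a handful of myofibrils
    (~30 measured pairs per group, residual scatter at the knockout TFL SD)
    and compared: slope-vs-zero per group, and the between-group slope test
    from the pooled interaction model.
    """
    rng = _rng(seed)
    measured = {}
    for group in ("+/Y", "-/Y"):
        spec = replace(presets.REGRESSION_POPULATIONS[group],
                       n_cells=n_fibrils, n_sarcomeres=n_sarcomeres,
                       tfl_noise_sd=0.09)
        measured[group] = _measured_pairs(spec, rng)
    cmp_ = stats.compare_regressions(*measured["+/Y"], *measured["-/Y"],
                                     labels=("+/Y", "-/Y"))
    return {
        "p_slope_nonzero": {"+/Y": cmp_.fit_a.p_slope_nonzero,
                            "-/Y": cmp_.fit_b.p_slope_nonzero},
        "p_slope_between": cmp_.p_slope,
        "n_pairs": {"+/Y": cmp_.fit_a.n, "-/Y": cmp_.fit_b.n},
    }


def recover_qpcr_pct(group: str, seed=0, noiseless: bool = True,
                     n_samples: int = 8) -> tuple[float, int]:
    """%N2B recovered by the qPCR element index from synthetic Ct tables."""
    truth = presets.QPCR_TRUTHS[group]
    if noiseless:
        truth = replace(truth, tech_noise_sd=0.0)
        n_samples = 1
    rng = _rng(seed)
    values = []
    for i in range(n_samples):
        table = simulate.simulate_ct_table(truth, sample_id=f"s{i}", rng=rng)
        (m,) = pct_n2b_from_ct(table, truth.efficiency)
        values.append(m.pct_n2b)
    return float(np.mean(values)), n_samples


def recover_gel_pct(group: str = "-/Y", seed=0, noise_sd: float = 0.0,
                    n_lanes: int = 1) -> tuple[float, int]:
    """%N2B recovered by lane densitometry from synthetic titin gels."""
    rng = _rng(seed)
    values = []
    for i in range(n_lanes):
        lane = simulate.simulate_gel_lane(
            presets.GEL_PCT_N2B[group], baseline_slope=0.05,
            baseline_offset=2.0, noise_sd=noise_sd, rng=rng,
            lane_id=f"lane{i}", group=group)
        values.append(quantify_lane(subtract_baseline(lane)).pct_n2b)
    return float(np.mean(values)), n_lanes


def recover_pca50(group: str = "+/Y", seed=0, noise_sd: float = 0.0,
                  ) -> tuple[float, int]:
    """pCa50 recovered by the Hill fit from a synthetic force-pCa curve."""
    grid = [7.0, 6.6, 6.4, 6.2, 6.1, 6.0, 5.9, 5.8, 5.6, 5.4, 5.0, 4.6]
    params = presets.FORCE_PCA[group]
    curve = simulate.simulate_force_pca(
        params["pca50"], params["n_hill"], params["f_max"],
        params["passive_force"], grid, noise_sd=noise_sd, rng=_rng(seed))
    fit = stats.fit_force_pca(curve)
    return fit.pca50, len(grid)
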