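"""Forward optical model and generator behaviour."""

import numpy as np
import pandas as pd
import pytest

import sarcometrics as sm
from sarcometrics.simulate import channel_field


def band_widths(profile, thin_amplitude, baseline):
    """H-band (coverage 0) and overlap (coverage 2) widths per profile, from
    a noiseless, PSF-free phalloidin trace between the outer Z lines."""
    cov = (profile.values - baseline) / thin_amplitude
    return cov


class TestSimulateProfile:
    def test_h_band_width_equals_sl_minus_2tfl(self, uniform_fibril, ideal_optics):
        # SL 2.2, TFL 0.98 -> zero-coverage gap of 0.24 um mid-sarcomere
        prof = sm.simulate_profile(uniform_fibril, ideal_optics,
                                   ("phalloidin",))["phalloidin"]
        cov = band_widths(prof, ideal_optics.thin_amplitude, ideal_optics.baseline)
        x = prof.positions + prof.origin[0]
        z = uniform_fibril.z_positions
        inner = (x > z[2]) & (x < z[3])  # one interior sarcomere
        gap = np.sum(cov[inner] < 0.5) * prof.spacing
        assert gap == pytest.approx(2.2 - 2 * 0.98, abs=prof.spacing)

    def test_overlap_band_width_equals_2tfl_minus_sl(self, ideal_optics):
        truth = sm.SarcomereGroundTruth.from_sl_tfl([1.5] * 5, [0.9] * 5)
        prof = sm.simulate_profile(truth, ideal_optics, ("phalloidin",))["phalloidin"]
        cov = band_widths(prof, ideal_optics.thin_amplitude, ideal_optics.baseline)
        x = prof.positions + prof.origin[0]
        z = truth.z_positions
        inner = (x > z[2]) & (x < z[3])
        overlap = np.sum(cov[inner] > 1.5) * prof.spacing
        assert overlap == pytest.approx(2 * 0.9 - 1.5, abs=prof.spacing)

    def test_boundary_case_uniform_coverage(self, ideal_optics):
        # SL 2.0, TFL 1.0: coverage exactly 1 between Z lines, no bands
        truth = sm.SarcomereGroundTruth.from_sl_tfl([2.0] * 4, [0.999999] * 4)
        prof = sm.simulate_profile(truth, ideal_optics, ("phalloidin",))["phalloidin"]
        cov = band_widths(prof, ideal_optics.thin_amplitude, ideal_optics.baseline)
        x = prof.positions + prof.origin[0]
        z = truth.z_positions
        interior = (x > z[0] + 0.1) & (x < z[-1] - 0.1)
        # away from the Z-boost spikes, coverage is 1 everywhere
        near_z = np.min(np.abs(x[:, None] - z[None, :]), axis=1) < 0.1
        flat = cov[interior & ~near_z]
        assert np.allclose(flat, 1.0, atol=1e-6)

    def test_geometry_conservation(self, ideal_optics, rng):
        # (H width) - (overlap width) == SL - 2 TFL for every sarcomere
        sl = rng.uniform(1.4, 2.6, 8)
        tfl = np.clip(0.35 * sl + 0.21 + rng.normal(0, 0.1, 8), 0.3, sl - 0.05)
        truth = sm.SarcomereGroundTruth.from_sl_tfl(sl, tfl)
        optics = sm.OpticalModelParams(psf_sigma=0.0, noise_sd=0.0,
                                       z_amplitude=0.0)  # pure coverage
        prof = sm.simulate_profile(truth, optics, ("phalloidin",))["phalloidin"]
        cov = band_widths(prof, optics.thin_amplitude, optics.baseline)
        x = prof.positions + prof.origin[0]
        z = truth.z_positions
        for i in range(truth.n_sarcomeres):
            inner = (x > z[i]) & (x < z[i + 1])
            h = np.sum(cov[inner] < 0.5) * prof.spacing
            ov = np.sum(cov[inner] > 1.5) * prof.spacing
            assert h - ov == pytest.approx(sl[i] - 2 * tfl[i], abs=2 * prof.spacing)
            assert min(h, ov) <= 2 * prof.spacing  # at most one band type

    def test_tmod_impulses_sit_on_coverage_edges(self, uniform_fibril, ideal_optics):
        profs = sm.simulate_profile(uniform_fibril, ideal_optics,
                                    ("phalloidin", "tmod1"))
        tmod = profs["tmod1"].values
        base = ideal_optics.baseline
        spikes = np.flatnonzero(tmod > base + 0.5 * ideal_optics.epitope_amplitude)
        cov = band_widths(profs["phalloidin"], ideal_optics.thin_amplitude, base)
        # coverage changes by one unit within a sample of each Tmod spike
        drops = np.flatnonzero(np.abs(np.diff(cov)) > 0.5)
        for s in spikes:
            assert np.min(np.abs(drops - s)) <= 1

    def test_too_short_fibril_rejected(self, clean_optics):
        truth = sm.SarcomereGroundTruth.from_sl_tfl([2.0, 2.0], [0.9, 0.9])
        with pytest.raises(ValueError, match="3 sarcomeres"):
            sm.simulate_profile(truth, clean_optics)

    def test_unknown_channel_rejected(self, uniform_fibril, clean_optics):
        with pytest.raises(ValueError, match="unknown channel"):
            sm.simulate_profile(uniform_fibril, clean_optics, ("gfp",))

    def test_deterministic_given_seed(self, uniform_fibril):
        optics = sm.OpticalModelParams(noise_sd=0.05)
        a = sm.simulate_profile(uniform_fibril, optics, rng=7)["phalloidin"]
        b = sm.simulate_profile(uniform_fibril, optics, rng=7)["phalloidin"]
        assert np.array_equal(a.values, b.values)


class TestSimulateImage:
    def test_zero_orientation_matches_profile(self, uniform_fibril, clean_optics):
        img, _ = sm.simulate_image([uniform_fibril], clean_optics, 0.0, 420,
                                   channels=("alpha_actinin",))
        row = img[0, 210, :]
        x = (np.arange(img.shape[2]) - (img.shape[2] - 1) / 2) * clean_optics.pixel_size
        center = 0.5 * (uniform_fibril.z_positions[0] + uniform_fibril.z_positions[-1])
        expected = channel_field(uniform_fibril, clean_optics, "alpha_actinin",
                                 x + center)
        assert np.max(np.abs(row - expected)) < 0.02 * np.ptp(expected)

    def test_empty_population_rejected(self, clean_optics):
        with pytest.raises(ValueError, match="empty population"):
            sm.simulate_image([], clean_optics, 0.0, 128)

    def test_truth_table_lists_every_sarcomere(self, uniform_fibril, clean_optics):
        _, table = sm.simulate_image([uniform_fibril], clean_optics, 10.0, 420)
        assert len(table) == uniform_fibril.n_sarcomeres
        assert np.allclose(table["sl_um"], 2.2)


class TestSimulatePopulation:
    def test_noiseless_tfl_lies_exactly_on_the_line(self):
        spec = sm.PopulationSpec(n_cells=5, n_sarcomeres=8, sl_mean=2.2,
                                 sl_sd=0.15, tfl_slope=0.35,
                                 tfl_intercept=0.21, tfl_noise_sd=0.0, seed=3)
        for cell in sm.simulate_population(spec):
            assert np.allclose(cell.tfl_values,
                               0.35 * cell.sl_values + 0.21, atol=1e-12)

    def test_zero_sl_sd_gives_identical_sarcomeres(self):
        spec = sm.PopulationSpec(n_cells=2, n_sarcomeres=6, sl_mean=1.9,
                                 sl_sd=0.0, tfl_slope=0.3, tfl_intercept=0.2,
                                 tfl_noise_sd=0.0, seed=0)
        for cell in sm.simulate_population(spec):
            # z positions come from a cumulative sum, so allow float round-off
            assert np.ptp(cell.sl_values) < 1e-12

    def test_sample_mean_within_3_se(self):
        # Monte-Carlo check: 10,000 SL draws
        spec = sm.PopulationSpec(n_cells=1000, n_sarcomeres=10, sl_mean=1.81,
                                 sl_sd=0.09, tfl_slope=0.35,
                                 tfl_intercept=0.21, tfl_noise_sd=0.0, seed=11)
        sl = np.concatenate([c.sl_values for c in sm.simulate_population(spec)])
        se = 0.09 / np.sqrt(sl.size)
        assert abs(sl.mean() - 1.81) < 3 * se

    def test_bit_reproducible_under_seed(self):
        spec = sm.PopulationSpec(n_cells=4, n_sarcomeres=6, sl_mean=1.7,
                                 sl_sd=0.2, tfl_slope=0.3, tfl_intercept=0.3,
                                 tfl_noise_sd=0.05, seed=99)
        a = sm.simulate_population(spec)
        b = sm.simulate_population(spec)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.z_positions, cb.z_positions)
            assert np.array_equal(ca.tfl_values, cb.tfl_values)

    def test_degenerate_tfl_law_rejected(self):
        spec = sm.PopulationSpec(n_cells=10, n_sarcomeres=10, sl_mean=1.8,
                                 sl_sd=0.05, tfl_slope=1.1, tfl_intercept=0.5,
                                 tfl_noise_sd=0.01, seed=1)
        with pytest.raises(ValueError, match="degenerate"):
            sm.simulate_population(spec)

    def test_affected_fraction_shortens_and_labels_cells(self):
        spec = sm.PopulationSpec(n_cells=200, n_sarcomeres=6, sl_mean=2.0,
                                 sl_sd=0.05, tfl_slope=0.35,
                                 tfl_intercept=0.21, tfl_noise_sd=0.0,
                                 affected_fraction=0.6, affected_sl_mean=1.5,
                                 seed=21)
        cells = sm.simulate_population(spec)
        affected = [c for c in cells if c.isoform_class == "N2B-dominant"]
        assert 0.5 < len(affected) / len(cells) < 0.7
        assert np.mean([c.sl_values.mean() for c in affected]) < 1.7


class TestSimulateGelLane:
    def test_area_ratio_9_to_1(self):
        lane = sm.simulate_gel_lane(90.0, band_centers=(80.0, 40.0))
        x = lane.positions
        split = 60.0
        a_n2ba = np.trapezoid(lane.profile[x < split], x[x < split])
        a_n2b = np.trapezoid(lane.profile[x >= split], x[x >= split])
        assert a_n2b / a_n2ba == pytest.approx(9.0, rel=1e-3)

    def test_pct_zero_is_single_n2ba_band(self):
        lane = sm.simulate_gel_lane(0.0, band_centers=(80.0, 40.0))
        x = lane.positions
        assert np.trapezoid(lane.profile[x > 60], x[x > 60]) < 1e-6 * 1000

    def test_trapezoid_recovers_band_areas(self):
        # quadrature oracle: each noiseless band integrates to its target
        pct = 90.0
        lane = sm.simulate_gel_lane(pct, band_centers=(80.0, 40.0),
                                    band_sigmas=(3.0, 3.0), total_area=1000.0)
        x = lane.positions
        for center, target in ((80.0, 900.0), (40.0, 100.0)):
            window = np.abs(x - center) <= 15.0
            area = np.trapezoid(lane.profile[window], x[window])
            assert area == pytest.approx(target, rel=1e-3)

    def test_unresolvable_bands_warn(self):
        with pytest.warns(UserWarning, match="unresolvable"):
            sm.simulate_gel_lane(50.0, band_centers=(52.0, 48.0),
                                 band_sigmas=(3.0, 3.0))

    def test_band_order_enforced(self):
        with pytest.raises(ValueError, match="migrates farther"):
            sm.simulate_gel_lane(50.0, band_centers=(40.0, 80.0))


class TestSimulateCtTable:
    @pytest.mark.parametrize("pct, expected_dct", [
        (75.0, 2.0),                     # -log2(0.25)
        (0.0, 0.0),                      # equal templates
        (93.7, -np.log2(1 - 0.937)),     # closed-form arithmetic
    ])
    def test_delta_ct_encodes_isoform_fraction(self, pct, expected_dct):
        table = sm.simulate_ct_table(sm.QpcrTruth(pct_n2b=pct))
        mean = table.groupby("target")["ct"].mean()
        assert mean["N2A_element"] - mean["N2B_element"] == \
            pytest.approx(expected_dct, abs=1e-12)

    def test_pct_100_censors_n2a(self):
        table = sm.simulate_ct_table(sm.QpcrTruth(pct_n2b=100.0))
        n2a = table[table["target"] == "N2A_element"]
        assert n2a["censored"].all()
        assert n2a["ct"].isna().all()

    def test_reference_pinned_at_ct_ref(self):
        table = sm.simulate_ct_table(sm.QpcrTruth(pct_n2b=50.0, ct_ref=22.5))
        assert (table.loc[table["target"] == "reference", "ct"] == 22.5).all()


class TestSimulateForcePca:
    GRID = [7.0, 6.6, 6.4, 6.2, 6.1, 6.0, 5.9, 5.8, 5.6, 5.4, 5.0, 4.6]

    def test_half_maximal_at_pca50(self):
        curve = sm.simulate_force_pca(6.0, 2.0, 30.0, 3.0, [7.0, 6.5, 6.0, 5.5, 5.0])
        at_mid = curve.active_force[curve.pca == 6.0]
        assert at_mid == pytest.approx(15.0)

    def test_low_calcium_limit_is_zero_active_force(self):
        curve = sm.simulate_force_pca(6.0, 2.0, 30.0, 3.0, [9.0, 8.5, 8.0])
        assert np.all(curve.active_force < 1e-3 * 30.0)

    def test_invalid_hill_coefficient(self):
        with pytest.raises(ValueError, match="Hill"):
            sm.simulate_force_pca(6.0, -1.0, 30.0, 0.0, self.GRID)

    def test_ascending_grid_rejected(self):
        with pytest.raises(ValueError, match="descending"):
            sm.simulate_force_pca(6.0, 2.0, 30.0, 0.0, [5.0, 6.0, 7.0])


class TestTransitionAndWallGenerators:
    def test_transition_series_shape_and_clipping(self, rng):
        df = sm.simulate.simulate_transition_series(
            ["P1", "P5"], {"wt": [1.0, 50.0], "ko": [1.0, 70.0]},
            n_per_stage=5, noise_sd=3.0, rng=rng)
        assert len(df) == 2 * 2 * 5
        assert df["pct_n2b"].between(0, 100).all()

    def test_wall_thickening_tidy_output(self, rng):
        df = sm.simulate.simulate_wall_thickening(
            {"wt": {"anterior": 50.0}}, {"wt": {"anterior": 10.0}},
            n_per_segment=6, rng=rng)
        assert list(df.columns) == ["group", "segment", "value"]
        assert len(df) == 6
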