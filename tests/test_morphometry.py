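"""Peak detection, SL/TFL measurement, orientation and aggregation."""

import numpy as np
import pandas as pd
import pytest

import sarcometrics as sm
from sarcometrics import morphometry as mm


def cosine_profile(period=1.8, length=36.0, spacing=0.05):
    x = np.arange(0.0, length, spacing)
    return sm.IntensityProfile(np.cos(2 * np.pi * x / period), spacing)


class TestDetectPeaks:
    def test_cosine_peaks_at_period_multiples(self):
        peaks = sm.detect_peaks(cosine_profile())
        k = np.arange(1, len(peaks) + 1)
        # interior maxima of cos(2 pi x / 1.8) sit at multiples of 1.8
        assert np.allclose(peaks.positions, 1.8 * k, atol=0.01)

    def test_flat_profile_yields_no_peaks(self):
        peaks = sm.detect_peaks(sm.IntensityProfile(np.ones(50), 0.05))
        assert len(peaks) == 0 and peaks.warning is not None

    def test_single_peak_flagged_not_raised(self):
        v = np.exp(-0.5 * ((np.arange(100) - 50) / 3.0) ** 2)
        peaks = sm.detect_peaks(sm.IntensityProfile(v, 0.05))
        assert len(peaks) == 1 and peaks.warning is not None

    def test_subpixel_refinement_beats_grid(self):
        # Gaussian centred between samples: parabolic refinement recovers it
        x = np.arange(0, 6, 0.05)
        center = 3.013
        v = np.exp(-0.5 * ((x - center) / 0.1) ** 2)
        peaks = sm.detect_peaks(sm.IntensityProfile(v, 0.05),
                                min_separation_um=0.5)
        assert abs(peaks.positions[0] - center) < 0.01

    def test_invalid_thresholds(self):
        prof = cosine_profile()
        with pytest.raises(ValueError):
            sm.detect_peaks(prof, prominence_frac=1.5)
        with pytest.raises(ValueError):
            sm.detect_peaks(prof, min_separation_um=-1.0)


class TestClassifyPeaks:
    def test_two_channel_labels_follow_channel(self, uniform_fibril, clean_optics):
        profs = sm.simulate_profile(uniform_fibril, clean_optics,
                                    ("alpha_actinin", "tmod1"))
        z = sm.detect_peaks(profs["alpha_actinin"])
        t = sm.detect_peaks(profs["tmod1"], min_separation_um=0.2)
        merged = sm.classify_peaks({"alpha_actinin": z, "tmod1": t})
        assert len(merged.select("z_disc")) == len(z)
        assert len(merged.select("pointed_end")) == len(t)
        # labels match ground truth channel assignment exactly
        assert np.allclose(np.sort(merged.select("z_disc").positions),
                           np.sort(z.positions))

    def test_combined_mode_splits_heights(self):
        peaks = sm.PeakSet(np.arange(5.0), np.array([10.0, 3.0, 10.0, 3.0, 10.0]))
        labelled = sm.classify_peaks(peaks, mode="combined")
        assert list(labelled.labels) == ["z_disc", "pointed_end", "z_disc",
                                         "pointed_end", "z_disc"]

    def test_combined_mode_equal_heights_error(self):
        peaks = sm.PeakSet(np.arange(4.0), np.full(4, 5.0))
        with pytest.raises(ValueError, match="cannot separate"):
            sm.classify_peaks(peaks, mode="combined")

    def test_two_channel_requires_both_channels(self):
        z = sm.PeakSet(np.array([0.0, 1.8]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="tmod1"):
            sm.classify_peaks({"alpha_actinin": z})


class TestMeasureSl:
    def test_consecutive_spacings(self):
        peaks = sm.PeakSet(np.array([0.0, 1.8, 3.6]), np.ones(3))
        assert np.allclose(sm.measure_sl(peaks), [1.8, 1.8])

    def test_guard_drops_implausible_spacings(self):
        peaks = sm.PeakSet(np.array([0.0, 0.1]), np.ones(2))
        assert sm.measure_sl(peaks).size == 0

    def test_fewer_than_two_peaks(self):
        assert sm.measure_sl(sm.PeakSet(np.array([1.0]), np.ones(1))).size == 0


class TestMeasureTfl:
    def test_single_z_both_flanks(self):
        z = sm.PeakSet(np.array([0.0]), np.ones(1))
        t = sm.PeakSet(np.array([-1.0, 1.0]), np.ones(2))
        assert np.allclose(sm.measure_tfl(z, t), [1.0, 1.0])

    def test_half_local_sl_guard(self):
        z = sm.PeakSet(np.array([0.0, 1.5]), np.ones(2))
        t = sm.PeakSet(np.array([0.9]), np.ones(1))  # 0.9 > 0.75 from left Z
        # nearest Z is the right one (0.6 < 0.75): kept as 0.6
        assert np.allclose(sm.measure_tfl(z, t), [0.6])

    def test_no_valid_pairs_is_empty_not_raised(self):
        z = sm.PeakSet(np.array([0.0, 1.0]), np.ones(2))
        t = sm.PeakSet(np.array([0.5]), np.ones(1))  # exactly half: rejected
        assert sm.measure_tfl(z, t).size == 0

    def test_pairs_table_carries_local_sl(self):
        z = sm.PeakSet(np.array([0.0, 2.0, 4.2]), np.ones(3))
        t = sm.PeakSet(np.array([0.9, 3.2]), np.ones(2))
        pairs = sm.measure_tfl_pairs(z, t)
        assert np.allclose(pairs["local_sl_um"], [2.0, 2.2])
        assert np.allclose(pairs["tfl_um"], [0.9, 1.0])


class TestMeasureSlFft:
    def test_pure_cosine(self):
        assert sm.measure_sl_fft(cosine_profile()) == pytest.approx(1.80, abs=0.01)

    def test_agrees_with_peak_estimator(self, clean_optics):
        truth = sm.SarcomereGroundTruth.from_sl_tfl([1.95] * 8, [0.9] * 8)
        prof = sm.simulate_profile(truth, clean_optics,
                                   ("alpha_actinin",))["alpha_actinin"]
        peak_sl = np.mean(sm.measure_sl(sm.detect_peaks(prof)))
        fft_sl = sm.measure_sl_fft(prof)
        assert abs(fft_sl - peak_sl) / peak_sl < 0.02

    def test_white_noise_rejected(self, rng):
        prof = sm.IntensityProfile(rng.normal(size=400), 0.05)
        with pytest.raises(ValueError):
            sm.measure_sl_fft(prof)


class TestClassifyPhenotype:
    @pytest.mark.parametrize("sl, tfl, expected", [
        (2.2, 0.98, "h_band_visible"),       # gap 0.24
        (1.5, 0.90, "overlap_bright_band"),  # overlap 0.3
        (1.9, 1.00, "no_resolvable_band"),   # overlap 0.1 below limit
    ])
    def test_banding_geometry(self, sl, tfl, expected):
        assert sm.classify_phenotype(sl, tfl) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sm.classify_phenotype(-1.0, 0.5)


class TestOrientationAndExtraction:
    def make_image(self, angle, seed=0, n_cells=1):
        spec = sm.PopulationSpec(n_cells=n_cells, n_sarcomeres=12,
                                 sl_mean=1.81, sl_sd=0.09, tfl_slope=0.35,
                                 tfl_intercept=0.21, tfl_noise_sd=0.03,
                                 seed=seed)
        truths = sm.simulate_population(spec)
        optics = sm.OpticalModelParams(noise_sd=0.05)
        img, table = sm.simulate_image(truths, optics, angle, 460, rng=seed,
                                       channels=("alpha_actinin",))
        return img[0], table, optics

    @pytest.mark.parametrize("angle", [0.0, 37.0, 126.0])
    def test_orientation_recovered_within_one_degree(self, angle):
        img, _, optics = self.make_image(angle)
        est = sm.estimate_orientation(img, pixel_size=optics.pixel_size)
        diff = min(abs(est - angle), 180 - abs(est - angle))
        assert diff < 1.0

    def test_uniform_noise_has_no_striations(self, rng):
        with pytest.raises(ValueError, match="no striations"):
            sm.estimate_orientation(rng.normal(size=(256, 256)))

    def test_round_trip_through_rotated_image(self):
        img, table, optics = self.make_image(37.0, seed=4)
        est = sm.estimate_orientation(img, pixel_size=optics.pixel_size)
        prof = sm.extract_profile(img, angle_deg=est,
                                  pixel_size=optics.pixel_size,
                                  averaging_width_px=8)
        sl = sm.measure_sl(sm.detect_peaks(prof))
        assert np.mean(sl) == pytest.approx(table["sl_um"].mean(), abs=0.01)

    def test_averaging_width_one_is_single_row(self, rng):
        img = rng.normal(size=(40, 60))
        prof = sm.extract_profile(img, start=(0.0, 17.0), end=(59.0, 17.0),
                                  averaging_width_px=1)
        assert np.allclose(prof.values, img[17, :])

    def test_diagonal_spacing_is_euclidean(self):
        img = np.zeros((50, 50))
        prof = sm.extract_profile(img, start=(0.0, 0.0), end=(30.0, 40.0),
                                  pixel_size=0.1)
        assert prof.length_um == pytest.approx(5.0, abs=0.01)  # 50 px * 0.1

    def test_endpoints_outside_image_rejected(self):
        img = np.zeros((20, 20))
        with pytest.raises(ValueError, match="inside"):
            sm.extract_profile(img, start=(0.0, 0.0), end=(25.0, 5.0))


class TestAggregateCells:
    def make_result(self, cell_id, sl, tfl=(), phenotype=None):
        return mm.MorphometryResult(cell_id, np.asarray(sl, float),
                                    np.asarray(tfl, float), phenotype)

    def test_single_cell_stats_equal_its_values(self):
        res = self.make_result("c0", [1.8, 1.8, 1.8])
        stats = sm.aggregate_cells([res], ["wt"])["wt"]
        assert stats.mean == pytest.approx(1.8)
        assert stats.n == 1

    def test_iqr_uses_linear_interpolation(self):
        results = [self.make_result(f"c{i}", [v]) for i, v in
                   enumerate([1.0, 2.0, 3.0, 4.0, 5.0])]
        stats = sm.aggregate_cells(results, ["g"] * 5)["g"]
        assert (stats.iqr_low, stats.iqr_high) == (2.0, 4.0)
        assert stats.median == 3.0

    def test_affected_fraction_counts_non_h_band(self):
        phenos = ["h_band_visible", "no_resolvable_band",
                  "overlap_bright_band", "h_band_visible"]
        results = [self.make_result(f"c{i}", [1.8], phenotype=p)
                   for i, p in enumerate(phenos)]
        stats = sm.aggregate_cells(results, ["g"] * 4)["g"]
        assert stats.affected_fraction == pytest.approx(0.5)


class TestEpitopeSpacing:
    def test_spacing_matches_forward_model(self):
        # N2BA titin at stretched SL, imaged with a structured-illumination
        # PSF so the closely spaced ex49 pair resolves
        sl = 2.6
        truth = sm.SarcomereGroundTruth.from_sl_tfl(
            [sl] * 6, [1.0] * 6, isoform_class="N2BA-dominant")
        optics = sm.OpticalModelParams(psf_sigma=0.05, noise_sd=0.0)
        profs = sm.simulate_profile(
            truth, optics, ("alpha_actinin", "titin_ex49", "titin_ex224"))
        z = sm.detect_peaks(profs["alpha_actinin"])
        e49 = sm.detect_peaks(profs["titin_ex49"], min_separation_um=0.15)
        e224 = sm.detect_peaks(profs["titin_ex224"], min_separation_um=0.15)
        table = sm.measure_epitope_spacing(e49, e224, z, optics.psf_sigma)
        expected = (0.25 - 0.10) + (0.15 - 0.05) * (sl - 2.0)
        assert not table.empty
        assert np.allclose(table["spacing_um"], expected, atol=0.025)
        assert table["resolvable"].all()

    def test_short_n2b_sarcomeres_flagged_unresolvable(self):
        # geometric spacing measured at high resolution but flagged against
        # the confocal PSF: bands merge below the FWHM
        sl = 1.6
        truth = sm.SarcomereGroundTruth.from_sl_tfl(
            [sl] * 6, [0.7] * 6, isoform_class="N2B-dominant")
        optics = sm.OpticalModelParams(psf_sigma=0.02, noise_sd=0.0)
        profs = sm.simulate_profile(
            truth, optics, ("alpha_actinin", "titin_ex49", "titin_ex224"))
        z = sm.detect_peaks(profs["alpha_actinin"])
        e49 = sm.detect_peaks(profs["titin_ex49"], min_separation_um=0.1)
        e224 = sm.detect_peaks(profs["titin_ex224"], min_separation_um=0.1)
        table = sm.measure_epitope_spacing(e49, e224, z, psf_sigma_um=0.10)
        assert not table.empty
        assert not table["resolvable"].any()

    def test_missing_channel_rejected(self):
        z = sm.PeakSet(np.array([0.0, 2.0]), np.ones(2))
        empty = sm.PeakSet(np.empty(0), np.empty(0))
        with pytest.raises(ValueError, match="ex224"):
            sm.measure_epitope_spacing(z, empty, z, 0.1)


class TestMeasureCell:
    def test_round_trip_noiseless(self, clean_optics, rng):
        sl = rng.uniform(2.3, 2.7, 10)
        # keep every pointed end short of min(SL)/2 so no pair is guarded out
        tfl = rng.uniform(0.9, 1.05, 10)
        truth = sm.SarcomereGroundTruth.from_sl_tfl(sl, tfl, "cell")
        profs = sm.simulate_profile(truth, clean_optics,
                                    ("alpha_actinin", "tmod1", "phalloidin"))
        res = sm.measure_cell(profs, "cell")
        # every sarcomere recovered to within half a sample spacing
        assert res.n_sarcomeres == 10
        assert np.max(np.abs(np.sort(res.sl_values) - np.sort(sl))) <= \
            0.5 * clean_optics.pixel_size
        assert res.tfl_values.size == 20
        assert abs(res.tfl_mean - tfl.mean()) <= 0.5 * clean_optics.pixel_size

    def test_monotonic_shift(self, clean_optics):
        base = np.full(8, 2.0)
        tfl = np.full(8, 0.9)
        for delta in (0.0, 0.15):
            truth = sm.SarcomereGroundTruth.from_sl_tfl(base + delta, tfl)
            profs = sm.simulate_profile(truth, clean_optics, ("alpha_actinin",))
            sl = sm.measure_sl(sm.detect_peaks(profs["alpha_actinin"]))
            assert np.allclose(sl, 2.0 + delta, atol=0.5 * clean_optics.pixel_size)

    def test_overlap_phenotype_detected_from_phalloidin(self, clean_optics):
        # Tmod1 distances cannot see overlap (TFL and SL-TFL coincide), so
        # the call must come from the phalloidin banding
        truth = sm.SarcomereGroundTruth.from_sl_tfl([1.5] * 6, [0.9] * 6)
        profs = sm.simulate_profile(truth, clean_optics,
                                    ("alpha_actinin", "tmod1", "phalloidin"))
        res = sm.measure_cell(profs)
        assert res.phenotype == "overlap_bright_band"

    def test_h_band_phenotype_from_phalloidin(self, clean_optics):
        truth = sm.SarcomereGroundTruth.from_sl_tfl([2.3] * 6, [1.0] * 6)
        profs = sm.simulate_profile(truth, clean_optics,
                                    ("alpha_actinin", "phalloidin"))
        res = sm.measure_cell(profs)
        assert res.phenotype == "h_band_visible"

    def test_marginal_band_phenotype_unresolved(self, clean_optics):
        truth = sm.SarcomereGroundTruth.from_sl_tfl([1.9] * 6, [0.97] * 6)
        profs = sm.simulate_profile(truth, clean_optics,
                                    ("alpha_actinin", "phalloidin"))
        res = sm.measure_cell(profs)
        assert res.phenotype == "no_resolvable_band"

    def test_requires_structural_channel(self):
        prof = sm.IntensityProfile(np.ones(10), 0.05, "tmod1")
        with pytest.raises(ValueError, match="structural channel"):
            sm.measure_cell({"tmod1": prof})
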