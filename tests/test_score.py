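"""Wavelet kernel, convolution, peak calling, mask, and per-cell scoring."""

import math

import numpy as np
import pytest

import fldqc
from fldqc.fragments import FLDHistogram
from fldqc.score import (
    PeakSet,
    ScoreConfig,
    build_scoring_mask,
    build_wavelet,
    call_peaks,
    convolve_fld,
    downsample_histogram,
    score_all,
    score_cell,
    score_histogram,
)
from tests.conftest import make_hist

SQRT_2PI = math.sqrt(2.0 * math.pi)


def brute_force_convolve(counts, kernel_values):
    """Independent O(n*m) same-mode zero-padded convolution."""
    n, m = len(counts), len(kernel_values)
    half = m // 2
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(m):
            k = i + half - j  # input index aligned with kernel tap j
            if 0 <= k < n:
                acc += counts[k] * kernel_values[j]
        out[i] = acc
    return out


class TestWavelet:
    def test_peak_value_is_gaussian_norm(self):
        w = build_wavelet(150.0, 0.4)
        center = len(w.values) // 2
        assert w.values[center] == pytest.approx(1.0 / (0.4 * SQRT_2PI), abs=1e-12)

    def test_half_wavelength_point_is_negligible(self):
        # at a(t-b) = pi the envelope exp(-pi^2/(2*0.16)) has killed the
        # cosine; t = b + 75 lies outside the sampled support entirely
        w = build_wavelet(150.0, 0.4)
        value = (
            math.cos(math.pi)
            / (0.4 * SQRT_2PI)
            * math.exp(-0.5 * math.pi**2 / 0.4**2)
        )
        assert abs(value) < 1e-12
        assert w.support[-1] < 75

    def test_even_symmetry(self):
        w = build_wavelet(150.0, 0.4)
        np.testing.assert_allclose(w.values, w.values[::-1], atol=1e-15)

    def test_edges_decayed_below_1e8_of_peak(self):
        w = build_wavelet(150.0, 0.4)
        peak = np.abs(w.values).max()
        assert abs(w.values[0]) < 1e-8 * peak and abs(w.values[-1]) < 1e-8 * peak
        assert len(w.values) % 2 == 1

    @pytest.mark.parametrize("wavelength,sigma", [(0, 0.4), (150, 0), (-10, 0.4)])
    def test_invalid_parameters_raise(self, wavelength, sigma):
        with pytest.raises(ValueError):
            build_wavelet(wavelength, sigma)


class TestConvolution:
    def test_zero_histogram_gives_zero_signal(self):
        h = make_hist({})
        w = build_wavelet()
        assert not convolve_fld(h, w).any()

    def test_unit_impulse_reproduces_kernel(self):
        h = make_hist({300: 1})
        w = build_wavelet()
        signal = convolve_fld(h, w)
        half = len(w.values) // 2
        np.testing.assert_allclose(
            signal[300 - half : 300 + half + 1], w.values, atol=1e-12
        )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        w = build_wavelet()
        for _ in range(5):
            counts = rng.integers(0, 50, size=1000)
            h = FLDHistogram("x", counts.astype(np.int64))
            np.testing.assert_allclose(
                convolve_fld(h, w), brute_force_convolve(counts, w.values), atol=1e-9
            )


class TestPeakCalling:
    def test_zero_signal_gives_empty_peakset(self):
        assert len(call_peaks(np.zeros(100))) == 0

    def test_constructed_maxima_found_in_order(self):
        signal = np.zeros(500)
        for pos, amp in [(50, 3.0), (200, 2.0), (400, 1.0)]:
            signal[pos] = amp
        peaks = call_peaks(signal, n_peaks=5, min_separation=100)
        assert list(peaks.positions) == [50, 200, 400]
        assert list(peaks.amplitudes) == [3.0, 2.0, 1.0]

    def test_equal_maxima_within_separation_keep_smaller_position(self):
        signal = np.zeros(200)
        signal[100] = signal[110] = 5.0
        peaks = call_peaks(signal, n_peaks=5, min_separation=50)
        assert list(peaks.positions) == [100]

    def test_negative_maxima_excluded(self):
        signal = -np.ones(100)
        signal[50] = -0.1  # local maximum but negative
        assert len(call_peaks(signal)) == 0

    def test_at_most_n_peaks(self):
        signal = np.zeros(1000)
        signal[10::100] = np.arange(10) + 1.0
        assert len(call_peaks(signal, n_peaks=5, min_separation=50)) == 5


class TestScoringMask:
    def test_center_value_matches_sum_of_densities(self):
        mask = build_scoring_mask()
        x = 200.0
        expected = sum(
            1.0 / (35.0 * SQRT_2PI) * math.exp(-0.5 * ((x - c) / 35.0) ** 2)
            for c in mask.centers
        )
        assert mask.values[200] == pytest.approx(expected, abs=1e-12)

    def test_total_mass_is_number_of_components(self):
        # five unit densities integrate to 5 when all tails lie inside the grid
        mask = build_scoring_mask(
            centers=(300, 500, 700, 900, 1100), sigma=35.0, l_max=1400
        )
        assert np.trapezoid(mask.values) == pytest.approx(5.0, abs=1e-6)

    def test_midpoint_between_two_centers(self):
        mask = build_scoring_mask(centers=(100, 300), sigma=35.0, l_max=400)
        expected = 2.0 / (35.0 * SQRT_2PI) * math.exp(-0.5 * (100.0 / 35.0) ** 2)
        assert mask.values[200] == pytest.approx(expected, rel=1e-9)

    def test_non_increasing_centers_raise(self):
        with pytest.raises(ValueError):
            build_scoring_mask(centers=(50, 50, 400, 600, 800))


class TestScoreCell:
    def test_single_peak_at_isolated_center(self):
        mask = build_scoring_mask(centers=(500,), sigma=35.0)
        peaks = PeakSet(np.array([500]), np.array([2.0]))
        assert score_cell(peaks, mask) == pytest.approx(
            2.0 / (35.0 * SQRT_2PI), abs=1e-9
        )

    def test_empty_peakset_scores_zero(self):
        mask = build_scoring_mask()
        assert score_cell(PeakSet(np.empty(0, dtype=int), np.empty(0)), mask) == 0.0

    def test_one_sigma_offset_attenuates_by_exp_half(self):
        mask = build_scoring_mask(centers=(500,), sigma=35.0)
        on = score_cell(PeakSet(np.array([500]), np.array([1.0])), mask)
        off = score_cell(PeakSet(np.array([535]), np.array([1.0])), mask)
        assert off / on == pytest.approx(math.exp(-0.5), abs=1e-9)


class TestDownsampling:
    def test_no_upsampling_below_target(self):
        h = make_hist({150: 30, 300: 20})
        assert downsample_histogram(h, 100, 0) is h

    def test_total_conserved_exactly(self):
        h = make_hist({150: 500, 300: 500})
        d = downsample_histogram(h, 100, 3)
        assert d.total == 100

    def test_single_bin_is_deterministic(self):
        h = make_hist({200: 1000})
        d = downsample_histogram(h, 10, 99)
        assert d.counts[200] == 10 and d.total == 10

    def test_reproducible_given_seed(self):
        h = make_hist({150: 500, 300: 300, 450: 200})
        a = downsample_histogram(h, 100, 7)
        b = downsample_histogram(h, 100, 7)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_invalid_target_raises(self):
        with pytest.raises(ValueError):
            downsample_histogram(make_hist({150: 10}), 0)


def synthetic_hist(theta, n, seed, barcode="BC"):
    lens = fldqc.sample_cell_lengths(fldqc.FLDModel(theta=theta), n, seed)
    return make_hist(lens, barcode=barcode)


class TestPipeline:
    def test_zero_fragment_cell_flagged(self):
        r = score_histogram(make_hist({}))
        assert r.fld_score == 0.0 and r.flag == "no_fragments"

    def test_below_target_cell_flagged_not_upsampled(self):
        r = score_histogram(synthetic_hist(1.0, 100, 1), ScoreConfig(target_n=5000))
        assert r.flag == "below_target" and not r.downsampled
        assert r.n_fragments_used == 100

    def test_scale_equivariance_without_downsampling(self):
        """k-fold histogram -> exactly k-fold score (why downsampling is needed)."""
        h = synthetic_hist(1.0, 500, 5)
        cfg = ScoreConfig(target_n=10**9)
        s1 = score_histogram(h, cfg).fld_score
        h5 = FLDHistogram(h.barcode, h.counts * 5)
        s5 = score_histogram(h5, cfg).fld_score
        assert s5 == pytest.approx(5.0 * s1, rel=1e-12)
        assert s1 > 0

    def test_flat_histogram_scores_far_below_periodic(self):
        """A constant FLD carries no periodicity: only boundary roll-off of
        the (positive-mean) kernel can produce peaks, so the score is a
        small fraction of a periodic cell's."""
        flat = FLDHistogram("flat", np.full(1001, 5, dtype=np.int64))
        cfg = ScoreConfig(target_n=10**9)
        s_flat = score_histogram(flat, cfg).fld_score
        s_periodic = score_histogram(synthetic_hist(1.0, 5005, 2), cfg).fld_score
        assert s_flat < 0.1 * s_periodic

    def test_all_zero_scores_exactly_zero(self):
        assert score_histogram(make_hist({})).fld_score == 0.0

    def test_identical_histograms_equal_scores(self):
        h1 = synthetic_hist(0.8, 2000, 9, "SAME")
        h2 = FLDHistogram("SAME", h1.counts.copy())
        r1 = score_histogram(h1)
        r2 = score_histogram(h2)
        assert r1.fld_score == r2.fld_score

    def test_parallel_bit_identical_to_serial(self):
        hists = {
            f"C{i}": synthetic_hist(0.5 + 0.1 * (i % 5), 8000, 100 + i, f"C{i}")
            for i in range(12)
        }
        serial = score_all(hists, n_workers=1)
        parallel = score_all(hists, n_workers=4)
        assert serial == parallel

    def test_mean_score_increases_with_periodicity(self):
        """Quick 3-point version of the monotonicity property (full sweep in
        the acceptance suite)."""
        rng = np.random.default_rng(17)
        means = []
        for theta in (0.0, 0.5, 1.0):
            scores = [
                score_histogram(
                    make_hist(
                        fldqc.sample_cell_lengths(fldqc.FLDModel(theta=theta), 5000, rng)
                    )
                ).fld_score
                for _ in range(20)
            ]
            means.append(np.mean(scores))
        assert means[0] < means[1] < means[2]


class TestScoreConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(wavelength=-1), dict(sigma=0), dict(target_n=0), dict(n_peaks=0)],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScoreConfig(**kwargs)
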