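"""Unit and oracle tests for the time-series feature operators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from neoncts import operators as ops


def windows_strategy(min_size=5, max_size=40):
    return arrays(np.float64, st.integers(min_size, max_size),
                  elements=st.floats(-50, 50, allow_nan=False,
                                     width=32))


# ---------------------------------------------------------------------------
# successive increases and motifs


class TestSuccessiveIncreases:
    def test_strictly_increasing_counts_n_minus_2(self):
        assert ops.successive_increases(np.arange(300.0)) == 298

    @pytest.mark.parametrize("x", [np.arange(300.0)[::-1], np.full(300, 7.0)])
    def test_decreasing_or_constant_is_zero(self, x):
        assert ops.successive_increases(x) == 0

    def test_ties_are_not_increases(self):
        # a tie interrupts the double increase
        assert ops.successive_increases(np.array([1.0, 2.0, 2.0, 3.0])) == 0

    def test_matches_bruteforce_on_short_windows(self, rng):
        def oracle(x):
            return sum(1 for i in range(len(x) - 2)
                       if x[i] < x[i + 1] < x[i + 2])

        for _ in range(200):
            n = int(rng.integers(3, 31))
            x = np.round(rng.standard_normal(n) * 3, 1)  # induces ties
            assert ops.successive_increases(x) == oracle(x)

    def test_too_short_is_missing(self):
        assert np.isnan(ops.successive_increases(np.array([1.0, 2.0])))

    def test_random_walk_null_mean_near_quarter(self, rng):
        """Symmetric random walks have independent increment signs, so the
        expected double-increase count of a 300-sample walk is 298/4."""
        walks = np.cumsum(rng.standard_normal((2000, 300)), axis=1)
        counts = [ops.successive_increases(w) for w in walks]
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 298 / 4) < 4 * se + 0.5


class TestMotifFrequencies:
    def test_strictly_increasing(self):
        f = ops.symbolic_motif_frequencies(np.arange(10.0))
        assert f["f_up_up"] == 1.0
        assert sum(f.values()) == pytest.approx(1.0)

    def test_constant(self):
        f = ops.symbolic_motif_frequencies(np.full(10, 2.0))
        assert f["f_same_same"] == 1.0

    def test_hand_enumerated_alternation(self):
        f = ops.symbolic_motif_frequencies(np.array([1.0, 2.0, 1.0, 2.0]))
        assert f["f_up_down"] == pytest.approx(0.5)
        assert f["f_down_up"] == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=50)
    @given(windows_strategy())
    def test_frequencies_sum_to_one(self, x):
        f = ops.symbolic_motif_frequencies(x)
        assert sum(f.values()) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# moving threshold


class TestMovingThreshold:
    def test_hand_computed_sequence(self):
        out = ops.moving_threshold(np.array([2.0, 0.0, 0.0]),
                                   rate_a=1.0, decay_b=0.1, prescored=True)
        # tested thresholds [1, 2, 1.8]: event only at the first point
        assert out["n_events"] == 1
        assert out["q_mean"] == pytest.approx(1.6)
        assert np.isnan(out["mean_gap"])

    def test_no_events_no_decay_keeps_threshold(self):
        out = ops.moving_threshold(np.full(50, 0.5), rate_a=1.0,
                                   decay_b=0.0, prescored=True)
        assert out["n_events"] == 0
        assert out["q_mean"] == pytest.approx(1.0)

    def test_geometric_decay_on_zero_signal(self):
        out = ops.moving_threshold(np.zeros(100), rate_a=0.5,
                                   decay_b=0.1, prescored=True)
        expected = np.mean(0.9 ** np.arange(100))
        assert out["n_events"] == 0
        assert out["q_mean"] == pytest.approx(expected)
        assert out["q_p50"] == pytest.approx(
            np.percentile(0.9 ** np.arange(100), 50))

    def test_constant_window_is_missing(self):
        out = ops.moving_threshold(np.full(300, 5.0))
        assert all(np.isnan(v) for v in out.values())

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError, match="rate_a"):
            ops.moving_threshold(np.zeros(10), rate_a=-1)
        with pytest.raises(ValueError, match="decay_b"):
            ops.moving_threshold(np.zeros(10), decay_b=1.0)

    def test_event_rate_and_gaps(self, rng):
        z = np.abs(rng.standard_normal(300))
        out = ops.moving_threshold(z, 0.5, 0.1, prescored=True)
        assert out["event_rate"] == out["n_events"] / 300
        assert 0 <= out["q_p05"] <= out["q_p50"] <= out["q_p95"]


# ---------------------------------------------------------------------------
# surprise


class TestSurprise:
    def test_constant_symbol_memory(self):
        out = ops.surprise(None, n_groups=3, memory_m=4,
                           symbols=np.zeros(9, dtype=int))
        assert out["mean_inv_p"] == pytest.approx(7 / 5)
        assert out["mean_log_inv_p"] == pytest.approx(np.log(7 / 5))

    def test_unseen_symbol_has_max_surprise(self):
        sym = np.array([0, 0, 0, 0, 1])
        out = ops.surprise(None, n_groups=3, memory_m=4, symbols=sym)
        assert out["mean_inv_p"] == pytest.approx(7.0)

    def test_alternating_two_symbols(self):
        sym = np.tile([0, 1], 20)
        out = ops.surprise(None, n_groups=3, memory_m=4, symbols=sym)
        # each step: symbol seen m/2 times in memory -> p = (m/2+1)/(m+3)
        assert out["mean_inv_p"] == pytest.approx(7 / 3)

    def test_window_shorter_than_memory_is_missing(self):
        out = ops.surprise(np.arange(10.0), memory_m=50)
        assert np.isnan(out["mean_inv_p"])

    def test_quantile_binning_path(self, rng):
        x = rng.standard_normal(300)
        out = ops.surprise(x, n_groups=3, memory_m=50)
        # probabilities are bounded by Laplace smoothing
        assert 53 / 51 / 1.04 < out["mean_inv_p"] < 53.0


# ---------------------------------------------------------------------------
# random walk


class TestRandomWalk:
    def test_zero_series_stays_at_origin(self):
        out = ops.random_walk_stats(np.zeros(20), 0.5)
        assert out["walker_mean"] == 0.0
        assert out["rms_residual"] == 0.0

    def test_full_coupling_lags_series_by_one(self, rng):
        x = rng.standard_normal(50)
        x[0] = 0.0
        out = ops.random_walk_stats(x, 1.0)
        # w_i = x_{i-1}: residual RMS equals RMS of first differences
        diffs = np.diff(x)
        assert out["rms_residual"] == pytest.approx(
            np.sqrt(np.sum(diffs ** 2) / x.size))

    def test_constant_series_closed_form(self):
        c = 3.0
        out = ops.random_walk_stats(np.full(4, c), 0.5)
        w = c * (1 - 0.5 ** np.arange(4))            # [0, c/2, 3c/4, 7c/8]
        assert out["walker_mean"] == pytest.approx(w.mean())
        assert out["walker_sd"] == pytest.approx(w.std(ddof=1))
        assert out["frac_walker_above"] == 0.0

    def test_invalid_coupling_raises(self):
        with pytest.raises(ValueError, match="coupling_p"):
            ops.random_walk_stats(np.zeros(10), 0.0)


# ---------------------------------------------------------------------------
# sample entropy


def sampen_bruteforce(x, m, r_frac):
    """O(n^2) template-counting oracle, straight from the definition."""
    x = np.asarray(x, dtype=float)
    r = r_frac * x.std()
    n = x.size

    def count(mm):
        c = 0
        for i in range(n - m):
            for j in range(i + 1, n - m):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    c += 1
        return c

    b, a = count(m), count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


class TestSampleEntropy:
    def test_alternating_matches_bruteforce_exactly(self):
        x = np.tile([1.0, 2.0], 5)
        got = ops.sample_entropy(x, 1, 0.5)
        want = sampen_bruteforce(x, 1, 0.5)
        assert got == pytest.approx(want, abs=1e-12)

    def test_matches_bruteforce_on_corpus(self, rng):
        """Both implementations against the oracle on windows of length
        <= 30 across the (m, r) grid."""
        for _ in range(40):
            n = int(rng.integers(8, 31))
            x = rng.standard_normal(n) * rng.uniform(0.5, 4.0)
            for m in (1, 2, 3):
                for r in (0.10, 0.15, 0.20, 0.25):
                    want = sampen_bruteforce(x, m, r)
                    got = ops.sample_entropy(x, m, r)
                    grid = ops.sample_entropy_many(x, [(m, r)])[(m, r)]
                    if np.isnan(want):
                        assert np.isnan(got) and np.isnan(grid)
                    else:
                        assert got == pytest.approx(want, abs=1e-12)
                        assert grid == pytest.approx(want, abs=1e-12)

    def test_near_constant_with_large_r_tends_to_zero(self, rng):
        x = 5.0 + rng.standard_normal(100) * 1e-9
        assert abs(ops.sample_entropy(x, 2, 10.0)) < 1e-6

    def test_translation_invariance(self, rng):
        x = rng.standard_normal(60)
        assert ops.sample_entropy(x, 2, 0.2) == pytest.approx(
            ops.sample_entropy(x + 123.4, 2, 0.2), rel=1e-12)

    def test_constant_window_is_missing(self):
        assert np.isnan(ops.sample_entropy(np.full(50, 3.0), 2, 0.2))

    def test_grid_shares_one_pass(self, rng):
        x = rng.standard_normal(120)
        pairs = [(m, r) for m in (1, 2, 3)
                 for r in (0.10, 0.15, 0.20, 0.25)]
        grid = ops.sample_entropy_many(x, pairs)
        for (m, r), v in grid.items():
            assert v == pytest.approx(ops.sample_entropy(x, m, r),
                                      abs=1e-12, nan_ok=True)


# ---------------------------------------------------------------------------
# distribution / correlation / stationarity / trend


class TestDistributionStats:
    def test_hand_computed_small_window(self):
        out = ops.distribution_stats(np.array([1.0, 2.0, 3.0, 4.0]))
        assert out["mean"] == pytest.approx(2.5)
        assert out["sd"] == pytest.approx(1.2910, abs=1e-4)
        assert out["range"] == 3.0
        assert out["iqr"] == pytest.approx(1.5)

    def test_constant_window(self):
        out = ops.distribution_stats(np.full(20, 3.7))
        assert out["sd"] == 0.0 and out["range"] == 0.0
        assert np.isnan(out["skewness"]) and np.isnan(out["kurtosis"])

    def test_mirroring_negates_skewness(self, rng):
        x = rng.gamma(2.0, size=200)
        assert ops.distribution_stats(-x)["skewness"] == pytest.approx(
            -ops.distribution_stats(x)["skewness"])

    def test_moments_match_scipy(self, rng):
        from scipy import stats
        x = rng.standard_normal(150)
        out = ops.distribution_stats(x)
        assert out["skewness"] == pytest.approx(stats.skew(x))
        assert out["kurtosis"] == pytest.approx(
            stats.kurtosis(x, fisher=False))


class TestAutocorrelation:
    def test_lag_zero_is_one(self, rng):
        assert ops.autocorrelation(rng.standard_normal(50), 0) == 1.0

    def test_alternating_signs(self):
        x = np.tile([1.0, -1.0], 150)
        n = x.size
        assert ops.autocorrelation(x, 1) == pytest.approx(-(n - 1) / n)

    def test_white_noise_lag1_small(self, rng):
        x = rng.standard_normal(300)
        assert abs(ops.autocorrelation(x, 1)) < 3 / np.sqrt(300)

    def test_nonlinear_moments_on_zscores(self, rng):
        x = rng.standard_normal(100)
        z = (x - x.mean()) / x.std()
        out = ops.nonlinear_autocorrelation(x)
        assert out["ac_nl_121"] == pytest.approx(np.mean(z[:-1] * z[1:] ** 2))


class TestStatAv:
    def test_linear_ramp_hand_value(self):
        out = ops.stationarity_statav(np.arange(1.0, 301.0), 5)
        # segment means {30.5, 90.5, ..., 270.5}; ratio ~ 1.094
        assert out["statav_mean"] == pytest.approx(1.094, abs=1e-3)

    def test_iid_noise_scales_as_inverse_sqrt_segment_length(self, rng):
        vals = [ops.stationarity_statav(rng.standard_normal(300),
                                        5)["statav_mean"]
                for _ in range(1000)]
        # segments of length 60: E[ratio] ~ 1/sqrt(60) ~ 0.129
        assert np.mean(vals) == pytest.approx(1 / np.sqrt(60), rel=0.1)

    def test_shuffling_destroys_trend(self, rng):
        x = np.arange(1.0, 301.0)
        shuffled = rng.permutation(x)
        assert (ops.stationarity_statav(shuffled, 5)["statav_mean"]
                < ops.stationarity_statav(x, 5)["statav_mean"])

    def test_constant_is_missing(self):
        assert np.isnan(ops.stationarity_statav(np.ones(300),
                                                5)["statav_mean"])


class TestTrendFit:
    def test_exact_line(self):
        x = 2.0 * np.arange(50) + 1.0
        out = ops.trend_fit(x)
        assert out["slope_per_step"] == pytest.approx(2.0)
        assert out["intercept"] == pytest.approx(1.0)
        assert out["residual_sd"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_has_zero_slope(self):
        assert ops.trend_fit(np.full(10, 4.0))["slope_per_step"] == 0.0

    def test_time_reversal_negates_slope(self, rng):
        x = rng.standard_normal(80) + 0.05 * np.arange(80)
        assert ops.trend_fit(x[::-1])["slope_per_step"] == pytest.approx(
            -ops.trend_fit(x)["slope_per_step"])


# ---------------------------------------------------------------------------
# spectral / wavelet / nonlinear


class TestSpectralBands:
    def test_pure_lf_sinusoid(self):
        t = np.arange(300) * 2.0                    # seconds at 0.5 Hz
        x = np.sin(2 * np.pi * 0.1 * t)             # 0.1 Hz -> LF band
        out = ops.spectral_band_features(x)
        assert out["lf_power"] >= 0.95 * out["total_power"]

    def test_parseval_total_power_is_variance(self, rng):
        x = rng.standard_normal(300) * 3 + 140
        out = ops.spectral_band_features(x)
        assert out["total_power"] == pytest.approx(x.var(), rel=1e-6)

    def test_white_noise_band_ratio(self, rng):
        ratios = [ops.spectral_band_features(
            rng.standard_normal(300))["lf_hf_ratio"] for _ in range(300)]
        # flat spectrum: ratio of band widths 0.11 / 0.10
        assert np.median(ratios) == pytest.approx(1.1, rel=0.15)

    def test_constant_window(self):
        out = ops.spectral_band_features(np.full(300, 9.0))
        assert out["total_power"] == 0.0
        assert np.isnan(out["lf_hf_ratio"])


class TestWaveletEnergies:
    def test_constant_has_no_detail_energy(self):
        out = ops.wavelet_level_energies(np.full(300, 5.0))
        for lev in range(1, 5):
            assert out[f"wav_d{lev}"] == pytest.approx(0.0, abs=1e-18)

    def test_alternating_concentrates_in_level1(self):
        x = np.tile([1.0, -1.0], 150)
        out = ops.wavelet_level_energies(x)
        total = sum(out.values())
        assert out["wav_d1"] / total > 0.999

    def test_orthonormal_energy_conservation(self, rng):
        x = rng.standard_normal(300) * 4 + 90
        out = ops.wavelet_level_energies(x)
        assert sum(out.values()) == pytest.approx(
            np.sum(x[:256] ** 2), rel=1e-9)


class TestFalseNearestNeighbors:
    def test_smooth_sine_embeds_at_dimension_two(self):
        x = np.sin(np.linspace(0, 20, 300))
        assert ops.false_nearest_neighbors(x)["fnn_m2"] <= 0.05

    def test_iid_noise_stays_false_at_dimension_one(self, rng):
        x = rng.standard_normal(300)
        assert ops.false_nearest_neighbors(x)["fnn_m1"] >= 0.5

    def test_fractions_bounded(self, rng):
        out = ops.false_nearest_neighbors(rng.standard_normal(100))
        assert all(0.0 <= v <= 1.0 for v in out.values())

    def test_kernel_matches_matrix_reference(self, rng):
        from neoncts.operators import (_chebyshev_template_counts,
                                       _fnn_fractions,
                                       _fnn_fractions_from_matrices)
        for _ in range(30):
            n = int(rng.integers(8, 60))
            x = rng.standard_normal(n)
            f1 = _fnn_fractions(x, 5, 10.0)
            f2 = _fnn_fractions_from_matrices(
                x, _chebyshev_template_counts(x, 5), 5, 10.0)
            assert np.array_equal(f1, f2)

    def test_constant_is_missing(self):
        out = ops.false_nearest_neighbors(np.full(50, 2.0))
        assert all(np.isnan(v) for v in out.values())
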