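"""Offline estimator: normalization, grids, ensemble means, spectra."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nse
from nse.errors import (
    BandTooNarrowError,
    DegenerateSignalError,
    WindowTooShortError,
)

from conftest import white_noise_signal


def naive_spectrum(x, grid):
    """Independent triple-loop transcription of the ensemble estimator.

    Builds each ensemble mean with explicit Python loops, forms the RMS
    ensemble power P_w = (1/w) e.e, and scales sqrt(n * P_w) by
    sqrt(n*w)/sqrt(N) to land on the segment-sum formulation.
    """
    xs = x.samples
    N = len(xs)
    out = []
    for w in grid.periods:
        w = int(w)
        n = N // w
        e = [0.0] * w
        for i in range(n):
            for j in range(w):
                e[j] += xs[i * w + j] / n
        p = sum(v * v for v in e) / w
        out.append(math.sqrt(n * p) * math.sqrt(n * w) / math.sqrt(N))
    return np.array(out)


class TestNormalize:
    def test_two_point_signal(self):
        out = nse.normalize_signal(nse.Signal([1.0, 3.0], 100.0))
        np.testing.assert_allclose(out.samples, [-1.0, 1.0])
        assert out.normalized and out.rate == 100.0

    def test_constant_signal_errors_with_channel_name(self):
        with pytest.raises(DegenerateSignalError, match="ch7"):
            nse.normalize_signal(nse.Signal([5.0, 5.0, 5.0], 10.0), channel="ch7")

    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=50))
    def test_idempotent_and_standardized(self, values):
        sig = nse.Signal(np.array(values), 100.0)
        if np.std(values) == 0:
            with pytest.raises(DegenerateSignalError):
                nse.normalize_signal(sig)
            return
        once = nse.normalize_signal(sig)
        assert abs(once.samples.mean()) < 1e-9
        assert abs(once.samples.var() - 1.0) < 1e-6
        twice = nse.normalize_signal(once)
        np.testing.assert_allclose(twice.samples, once.samples, atol=1e-9)

    def test_normalized_flag_is_checked(self):
        with pytest.raises(ValueError, match="normalized"):
            nse.Signal([0.0, 5.0, 1.0], 10.0, normalized=True)


class TestPeriodGrid:
    @pytest.mark.parametrize(
        "rate,f_lo,f_hi,w_first,w_last,count",
        [
            (977, 3, 12, 325, 81, 245),
            (100, 3, 12, 33, 8, 26),
            (1000, 3, 12, 333, 83, 251),
        ],
    )
    def test_floor_arithmetic(self, rate, f_lo, f_hi, w_first, w_last, count):
        grid = nse.build_period_grid(rate, f_lo, f_hi)
        assert grid.periods[0] == w_first
        assert grid.periods[-1] == w_last
        assert len(grid) == count

    def test_frequencies_are_exact_quotients(self):
        grid = nse.build_period_grid(1000.0, 3.0, 12.0)
        assert grid.frequencies[0] == 1000.0 / 333
        assert grid.frequencies[-1] == 1000.0 / 83
        assert np.all(np.diff(grid.frequencies) > 0)

    def test_empty_grid_raises(self):
        # floor monotonicity means build_period_grid can't produce an empty
        # grid from a valid band; the container itself still rejects one
        with pytest.raises(BandTooNarrowError):
            nse.PeriodGrid(np.array([], dtype=np.int64), np.array([]),
                           100.0, (3.0, 12.0))

    def test_invalid_band_ordering(self):
        with pytest.raises(ValueError):
            nse.build_period_grid(977.0, 12.0, 3.0)


class TestSegmentsAndEnsemble:
    @pytest.mark.parametrize(
        "N,w,n", [(8192, 81, 101), (8192, 325, 25), (8, 8, 1)]
    )
    def test_segment_count(self, N, w, n):
        assert nse.segment_count(N, w) == n

    def test_window_too_short(self):
        with pytest.raises(WindowTooShortError):
            nse.segment_count(10, 11)

    def test_tiled_segment_recovered_exactly(self, rng):
        s = rng.standard_normal(7)
        x = nse.Signal(np.tile(s, 5), 100.0)
        em = nse.ensemble_mean(x, 7)
        np.testing.assert_array_equal(em.values, s)
        assert em.n == 5

    def test_alternating_signal(self):
        x = nse.Signal([2.0, -2.0, 2.0, -2.0], 10.0)
        em = nse.ensemble_mean(x, 2)
        np.testing.assert_array_equal(em.values, [2.0, -2.0])
        assert em.n == 2

    def test_trailing_remainder_discarded(self, rng):
        xs = rng.standard_normal(10)
        em = nse.ensemble_mean(nse.Signal(xs, 10.0), 3)
        expected = (xs[0:3] + xs[3:6] + xs[6:9]) / 3
        np.testing.assert_allclose(em.values, expected)

    def test_matches_naive_double_loop(self, rng):
        xs = rng.standard_normal(53)
        for w in (1, 2, 7, 26, 53):
            em = nse.ensemble_mean(nse.Signal(xs, 10.0), w)
            n = 53 // w
            naive = [
                sum(xs[i * w + j] for i in range(n)) / n for j in range(w)
            ]
            np.testing.assert_allclose(em.values, naive, rtol=1e-12)


class TestOfflineSpectrum:
    def test_zero_signal_gives_zero_spectrum(self, small_grid):
        x = nse.Signal(np.zeros(200), 100.0)
        s = nse.nse_spectrum_offline(x, small_grid)
        assert np.all(s.values == 0)

    def test_matches_naive_transcription(self, small_grid, rng):
        for n in (200, 777, 1500):
            x = white_noise_signal(rng, n, rate=100.0)
            fast = nse.nse_spectrum_offline(x, small_grid)
            np.testing.assert_allclose(
                fast.values, naive_spectrum(x, small_grid), rtol=1e-9
            )

    def test_periodic_peak_closed_form(self, grid977, rng):
        # period 128 divides N=8192 exactly: S at w0 must be sqrt(n)
        w0, n = 128, 64
        template = rng.standard_normal(w0)
        x = nse.normalize_signal(nse.Signal(np.tile(template, n), 977.0))
        s = nse.nse_spectrum_offline(x, grid977)
        s_w0 = s.values[grid977.periods == w0][0]
        assert s_w0 == pytest.approx(math.sqrt(n), rel=1e-6)
        assert grid977.periods[np.argmax(s.values)] == w0

    def test_white_noise_baseline_near_unity(self, grid977, rng):
        means = [
            nse.nse_spectrum_offline(
                white_noise_signal(rng, 8192), grid977
            ).values.mean()
            for _ in range(20)
        ]
        assert all(0.8 <= m <= 1.2 for m in means)

    def test_signal_shorter_than_longest_period(self, grid977):
        with pytest.raises(WindowTooShortError):
            nse.nse_spectrum_offline(nse.Signal(np.ones(100), 977.0), grid977)


class TestHalvedSpectrum:
    def test_exact_when_segment_counts_even(self, rng):
        # N=400, w=100: n=4 = 2*n_2w, the shortcut is exact
        grid = nse.PeriodGrid(
            np.array([200, 100]), np.array([2.0, 4.0]), 400.0, (2.0, 4.0)
        )
        x = white_noise_signal(rng, 400, rate=400.0)
        direct = nse.nse_spectrum_offline(x, grid)
        halved = nse.nse_spectrum_offline_halved(x, grid)
        np.testing.assert_array_equal(direct.values, halved.values)

    def test_full_grid_agreement_where_counts_match(self, grid977, rng):
        x = white_noise_signal(rng, 8192)
        direct = nse.nse_spectrum_offline(x, grid977)
        halved = nse.nse_spectrum_offline_halved(x, grid977)
        for i, w in enumerate(grid977.periods):
            w = int(w)
            if 2 * w in grid977.periods and (8192 // w) == 2 * (8192 // (2 * w)):
                np.testing.assert_allclose(
                    halved.values[i], direct.values[i], rtol=1e-12
                )

    def test_odd_count_discrepancy_is_one_segment(self, rng):
        # N=8192, w=100: n=81 odd, the halved path drops segment 81
        xs = white_noise_signal(rng, 8192).samples
        w = 100
        direct_sums = xs[:8100].reshape(81, w).sum(axis=0)
        truncated_sums = xs[:8000].reshape(80, w).sum(axis=0)
        grid = nse.PeriodGrid(
            np.array([200, 100]), 8192.0 / np.array([200, 100]),
            8192.0, (40.0, 82.0),
        )
        x = nse.Signal(xs, 8192.0)
        halved = nse.nse_spectrum_offline_halved(x, grid)
        expected_w100 = math.sqrt(float(truncated_sums @ truncated_sums)) / math.sqrt(8192)
        assert halved.values[1] == pytest.approx(expected_w100, rel=1e-12)
        direct_w100 = math.sqrt(float(direct_sums @ direct_sums)) / math.sqrt(8192)
        assert halved.values[1] != direct_w100
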