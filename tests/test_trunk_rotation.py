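"""AMPD peak detection and the trunk-rotation (ATR) pipeline."""

import math

import numpy as np
import pytest

from scolioscreen.errors import BimodalPeakError, DomainError
from scolioscreen.synth import gen_sagittal_case
from scolioscreen.trunk_rotation import (
    AMPDResult,
    ampd_peaks,
    atr_angle,
    compute_lms,
    detrend_linear,
    filter_to_two_peaks,
    measure_atr,
)


def cosine_train(n_peaks, period, phase_frac=0.75):
    """Cosine with maxima well inside the scalogram's border blind zone."""
    N = int(round((n_peaks + 0.5) * period))
    j = np.arange(N)
    x = np.cos(2 * np.pi * (j - phase_frac * period) / period)
    true = np.array([phase_frac * period + m * period for m in range(n_peaks)])
    return x, true


class TestDetrend:
    def test_pure_line_becomes_zero(self):
        t = np.arange(100.0)
        assert np.allclose(detrend_linear(3.0 + 0.7 * t), 0.0, atol=1e-9)

    def test_line_plus_sine_leaves_the_sine(self):
        """Subtracting the closed-form regression line (slope = cov/var)
        recovers the oscillation with its amplitude intact."""
        t = np.arange(400.0)
        sine = 5.0 * np.sin(2 * np.pi * t / 50)
        x = 2.0 - 0.1 * t + sine
        slope = np.sum((t - t.mean()) * (x - x.mean())) / np.sum((t - t.mean()) ** 2)
        expected = x - (x.mean() + slope * (t - t.mean()))
        out = detrend_linear(x)
        assert np.allclose(out, expected, atol=1e-9)
        assert np.ptp(out) == pytest.approx(np.ptp(sine), rel=0.15)

    def test_output_has_zero_mean_and_slope(self, rng):
        x = rng.normal(0, 1, 500)
        out = detrend_linear(x)
        t = np.arange(500.0)
        coef = np.polynomial.polynomial.polyfit(t, out, 1)
        assert abs(out.mean()) < 1e-9
        assert abs(coef[1]) < 1e-9


class TestLMS:
    def test_hand_signal_zero_pattern(self):
        """x = (0,1,0,2,0): local maxima at indices 1 and 3 for scale 1 only;
        at scale 2 index 2 fails the comparison."""
        lms = compute_lms(np.array([0.0, 1, 0, 2, 0]), rng_seed=7)
        L, N = lms.M.shape
        assert (L, N) == (2, 5)
        zeros = {(k, i) for k in range(L) for i in range(N) if lms.M[k, i] == 0.0}
        assert zeros == {(0, 1), (0, 3)}
        nonzero = lms.M[lms.M != 0]
        assert np.all((nonzero >= 1.0) & (nonzero < 2.0))  # r + alpha, r in [0,1)
        assert lms.gamma.shape == (2,)
        assert lms.lam == 1

    def test_strictly_increasing_signal_has_no_zeros(self):
        lms = compute_lms(np.arange(30.0), rng_seed=0)
        assert np.all(lms.M != 0)

    def test_lambda_matches_brute_force_scan(self):
        """lambda maximises the number of surviving local maxima, verified by
        an independent double-loop count over every scale."""
        x, _ = cosine_train(6, 100)
        x = detrend_linear(x)
        N = len(x)
        L = math.ceil(N / 2) - 1
        counts = []
        for k in range(1, L + 1):
            z = 0
            for j in range(k, N - k):
                if x[j] > x[j - k] and x[j] >= x[j + k]:
                    z += 1
            counts.append(N - z)
        expected_lam = int(np.argmin(counts)) + 1
        assert compute_lms(x, rng_seed=0).lam == expected_lam
        assert 2 * expected_lam <= 100  # window no longer than the period

    def test_too_short_signal_raises(self):
        with pytest.raises(DomainError):
            compute_lms(np.array([1.0, 2.0]))


class TestAMPD:
    def test_monotone_ramp_has_no_peaks(self):
        assert ampd_peaks(np.linspace(0, 1, 64)).n_peaks == 0

    def test_noiseless_cosine_peaks_at_analytic_maxima(self):
        for n_peaks, period in ((5, 100), (3, 200), (10, 80)):
            x, true = cosine_train(n_peaks, period)
            res = ampd_peaks(detrend_linear(x))
            assert res.n_peaks == n_peaks
            assert np.abs(res.peak_indices - np.round(true)).max() <= 1

    def test_every_reported_peak_is_a_local_maximum(self, rng):
        """Neighbour-comparison oracle on random smooth signals."""
        for i in range(20):
            g = np.random.default_rng(1000 + i)
            N = 600
            j = np.arange(N)
            x = sum(
                g.uniform(0.5, 1.5) * np.sin(2 * np.pi * g.uniform(2, 6) * j / N + g.uniform(0, 7))
                for _ in range(int(g.integers(2, 5)))
            )
            for p in ampd_peaks(x).peak_indices:
                assert 0 < p < N - 1
                assert x[p] > x[p - 1] and x[p] >= x[p + 1]

    def test_peak_set_is_seed_invariant(self):
        for i in range(10):
            g = np.random.default_rng(2000 + i)
            N = 500
            j = np.arange(N)
            x = sum(
                g.uniform(0.5, 1.5) * np.sin(2 * np.pi * g.uniform(2, 6) * j / N + g.uniform(0, 7))
                for _ in range(3)
            )
            a = ampd_peaks(x, rng_seed=1).peak_indices
            b = ampd_peaks(x, rng_seed=31337).peak_indices
            assert np.array_equal(a, b)

    def test_sigma_zero_at_reported_peaks(self):
        x, _ = cosine_train(4, 120)
        res = ampd_peaks(detrend_linear(x))
        assert isinstance(res, AMPDResult)
        assert np.all(res.sigma[res.peak_indices] <= 1e-12)
        assert np.all(np.diff(res.peak_indices) > 0)


class TestFilter:
    def _result(self, peaks):
        return AMPDResult(peak_indices=np.asarray(peaks), sigma=np.array([]), lam=5, seed=0)

    def test_two_peaks_pass_through(self):
        h = np.zeros(100)
        assert filter_to_two_peaks(self._result([20, 70]), h) == (20, 70)

    def test_noise_spike_rejected_in_favour_of_bumps(self):
        cols = np.arange(300.0)
        h = (
            40 * np.exp(-((cols - 90) ** 2) / (2 * 20**2))
            + 30 * np.exp(-((cols - 210) ** 2) / (2 * 20**2))
        )
        h[150] += 3.0  # narrow spurious spike between the bumps
        peaks = [90, 150, 210]
        pa, pb = filter_to_two_peaks(self._result(peaks), h)
        assert (pa, pb) == (90, 210)

    def test_single_peak_raises(self):
        with pytest.raises(BimodalPeakError):
            filter_to_two_peaks(self._result([50]), np.zeros(100))

    def test_no_separated_pair_raises(self):
        h = np.zeros(100)
        h[[48, 50, 52]] = (1.0, 1.2, 1.1)
        with pytest.raises(BimodalPeakError):
            filter_to_two_peaks(self._result([48, 50, 52]), h)


class TestATRAngle:
    @pytest.mark.parametrize(
        "pa,pb,expected",
        [
            ((0, 10), (50, 10), 0.0),
            ((0, 0), (10, 10), 45.0),
            ((0, 0), (math.sqrt(3), 1), 30.0),
        ],
    )
    def test_known_geometries(self, pa, pb, expected):
        assert atr_angle(pa, pb) == pytest.approx(expected, abs=1e-9)

    def test_equal_columns_raise(self):
        with pytest.raises(DomainError):
            atr_angle((5, 0), (5, 10))


class TestMeasureATR:
    def test_symmetric_back_measures_zero(self):
        case = gen_sagittal_case(0.0)
        result = measure_atr(case.mask, operator="prewitt")
        assert result.atr_deg <= 0.5

    def test_known_rotation_recovered(self):
        case = gen_sagittal_case(10.0)
        result = measure_atr(case.mask, operator="prewitt")
        assert result.atr_deg == pytest.approx(10.0, abs=1.0)
        assert result.peak_a[0] < result.peak_b[0]

    def test_operators_agree_on_clean_mask(self):
        case = gen_sagittal_case(8.0)
        angles = [
            measure_atr(case.mask, operator=op).atr_deg
            for op in ("roberts", "prewitt", "log")
        ]
        assert max(angles) - min(angles) <= 1.0

    def test_result_records_intermediates(self):
        case = gen_sagittal_case(5.0)
        result = measure_atr(case.mask, operator="roberts")
        for key in ("profile", "signal_raw", "signal_detrended", "ampd"):
            assert key in result.intermediates
        d = result.to_dict()
        assert set(d) == {"atr_deg", "peaks", "operator", "n_peaks_raw", "lambda", "seed"}

    def test_blank_mask_fails(self):
        from scolioscreen.errors import EmptyProfileError

        with pytest.raises((BimodalPeakError, EmptyProfileError)):
            measure_atr(np.zeros((50, 50)), operator="prewitt")
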