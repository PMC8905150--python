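import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from antsync import ActivityTrace
from antsync import analysis as an
from antsync.fixtures import FixtureSpec, make_sinusoid_mix

from conftest import brute_force_prominent_peaks


def _trace(values, dt=30.0):
    return ActivityTrace(np.asarray(values, float), dt=dt)


class TestGaussianSmooth:
    def test_preserves_constants(self):
        out = an.gaussian_smooth(_trace(np.full(100, 3.7)))
        assert np.allclose(out.values, 3.7)

    def test_impulse_response_is_normalised_kernel(self):
        x = np.zeros(15)
        x[7] = 1.0
        out = an.gaussian_smooth(_trace(x), window=15)
        # response to a unit impulse is the (edge-renormalised) kernel itself
        half = 7
        k = np.exp(-0.5 * (np.arange(-half, half + 1) / 3.0) ** 2)
        den = np.convolve(np.ones(15), k, mode="same")
        assert np.allclose(out.values, k / den)
        assert out.values.argmax() == 7

    def test_reduces_variance_and_keeps_peak_location(self, rng):
        noise = rng.normal(size=400)
        out = an.gaussian_smooth(_trace(noise))
        assert out.values.var() < noise.var()
        # isolated symmetric peak stays put
        x = np.exp(-0.5 * ((np.arange(200) - 100) / 6.0) ** 2)
        sm = an.gaussian_smooth(_trace(x))
        assert sm.values.argmax() == 100

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            an.gaussian_smooth(_trace(np.arange(10.0)), window=15)


class TestMinmaxNormalize:
    def test_affine_example(self):
        out = an.minmax_normalize(_trace([2, 4, 6]))
        assert np.allclose(out.values, [0, 0.5, 1])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=50).filter(
        lambda v: max(v) > min(v)))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_bounded(self, values):
        once = an.minmax_normalize(_trace(values))
        twice = an.minmax_normalize(once)
        assert np.allclose(once.values, twice.values)
        assert once.values.min() == 0.0 and once.values.max() == 1.0

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            an.minmax_normalize(_trace(np.ones(10)))


class TestDetectPeaks:
    def test_monotone_series_has_no_peaks(self):
        assert an.detect_peaks(_trace(np.linspace(0, 1, 50))).size == 0

    def test_tall_peaks_over_zero_baseline(self):
        x = np.zeros(21)
        x[[3, 9, 15]] = [1.0, 0.9, 0.8]
        assert list(an.detect_peaks(_trace(x), 0.2)) == [3, 9, 15]

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(100, 500)
            x = rng.random(n)
            got = an.detect_peaks(_trace(x), 0.2)
            expected = brute_force_prominent_peaks(x, 0.2)
            assert np.array_equal(got, expected)


class TestIbiCv:
    def test_perfectly_periodic_train(self):
        s = an.ibi_cv([0, 600, 1200, 1800])
        assert s.mean_ibi == 600 and s.cv == 0.0

    def test_hand_calculation(self):
        # intervals {100, 200, 300}: mean 200, sample sd 100
        s = an.ibi_cv([0, 100, 300, 600])
        assert s.mean_ibi == pytest.approx(200)
        assert s.cv == pytest.approx(np.std([100, 200, 300], ddof=1) / 200)

    def test_exponential_intervals_cv_near_one(self, rng):
        times = np.cumsum(rng.exponential(2382, size=1001))
        assert an.ibi_cv(times).cv == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("times", [[0, 10], [0], [0, 10, 5]])
    def test_invalid_trains_rejected(self, times):
        with pytest.raises(ValueError):
            an.ibi_cv(times)


class TestDetrendPoly:
    def test_quartic_self_annihilation(self):
        t = np.arange(300, dtype=float)
        x = 1e-8 * (t - 150) ** 4 - 2e-5 * (t - 150) ** 2 + 3
        out = an.detrend_poly(_trace(x))
        assert np.max(np.abs(out.values)) < 1e-6 * np.max(np.abs(x))

    def test_recovers_sinusoid_under_quartic(self):
        t = np.arange(0, 35 * 3600, 30.0)
        sine = np.sin(2 * np.pi * t / 5040)
        trend = 1e-17 * (t - t.mean()) ** 4
        out = an.detrend_poly(ActivityTrace(sine + trend, dt=30.0))
        r = np.corrcoef(out.values, sine)[0, 1]
        assert r > 0.99
        assert abs(out.values.mean()) < 1e-8


class TestLombScargle:
    def test_single_tone(self):
        tr, _ = make_sinusoid_mix(FixtureSpec(
            kind="sinusoid_mix", duration=9 * 3600, dt=30, components=[(20 * 60, 1, 0)]))
        sp = an.lomb_scargle(tr)
        assert sp.dominant_period == pytest.approx(20 * 60, rel=0.02)

    def test_two_tone_35h_record_shows_two_peaks(self):
        # 84 min and 228 min rhythms co-occurring in one long record
        tr, _ = make_sinusoid_mix(FixtureSpec(
            kind="sinusoid_mix", duration=35 * 3600, dt=30,
            components=[(84 * 60, 1, 0), (228 * 60, 1, 1.0)]))
        sp = an.lomb_scargle(tr)
        periods = sorted([sp.dominant_period, sp.secondary_period])
        assert periods[0] == pytest.approx(84 * 60, rel=0.05)
        assert periods[1] == pytest.approx(228 * 60, rel=0.05)
        assert sp.secondary_ratio > 0.5

    def test_white_noise_not_significant_vs_shuffled_null(self, rng):
        x = rng.normal(size=1080)
        tr = _trace(x)
        peak = an.lomb_scargle(tr).power.max()
        null = [an.lomb_scargle(_trace(rng.permutation(x))).power.max()
                for _ in range(50)]
        # the unshuffled maximum is just another draw from the shuffled null
        assert peak < np.quantile(null, 0.99) * 1.5


class TestAggregateSpectra:
    def _spectrum(self, centre, grid=None):
        periods = grid if grid is not None else np.geomspace(300, 5 * 3600, 500)
        power = np.exp(-0.5 * ((np.log(periods) - np.log(centre)) / 0.05) ** 2)
        return an._make_spectrum(periods, power, "synthetic")

    def test_single_spectrum_rescaled_identity(self):
        sp = self._spectrum(1200)
        agg = an.aggregate_spectra([sp])
        assert agg.power.max() == pytest.approx(1.0)
        assert agg.dominant_period == sp.dominant_period

    def test_two_disjoint_peaks_sum(self):
        agg = an.aggregate_spectra([self._spectrum(1200), self._spectrum(9000)])
        assert agg.power.max() == pytest.approx(1.0, abs=0.05)
        assert agg.secondary_ratio > 0.9

    def test_shared_peak_dominates_eight_records(self, rng):
        # eight records share a 3.8 h rhythm; idiosyncratic peaks differ
        common = 3.8 * 3600
        spectra = []
        for _ in range(8):
            idio = np.exp(rng.uniform(np.log(600), np.log(7000)))
            periods = np.geomspace(300, 6 * 3600, 500)
            power = (np.exp(-0.5 * ((np.log(periods) - np.log(common)) / 0.05) ** 2)
                     + np.exp(-0.5 * ((np.log(periods) - np.log(idio)) / 0.05) ** 2))
            spectra.append(an._make_spectrum(periods, power, "synthetic"))
        agg = an.aggregate_spectra(spectra)
        assert agg.dominant_period == pytest.approx(common, rel=0.05)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            an.aggregate_spectra([])


class TestBirhythmicity:
    def _two_tone_spectrum(self, ratio_power, factor=2.0):
        periods = np.geomspace(300, 10_000, 800)
        power = (np.exp(-0.5 * ((np.log(periods) - np.log(1200)) / 0.04) ** 2)
                 + ratio_power * np.exp(
                     -0.5 * ((np.log(periods) - np.log(1200 * factor)) / 0.04) ** 2))
        return an._make_spectrum(periods, power, "synthetic")

    def test_single_tone_monorhythmic(self):
        assert an.birhythmicity_index(self._two_tone_spectrum(0.0)) == "monorhythmic"

    def test_equal_power_two_tone_birhythmic(self):
        sp = self._two_tone_spectrum(0.95)
        assert an.birhythmicity_index(sp) == "birhythmic"
        assert an.subharmonic_birhythmic(sp)

    def test_subharmonic_detector_rejects_near_neighbour(self):
        # a secondary hump 1.3x away is peak broadening, not a second rhythm
        sp = self._two_tone_spectrum(0.9, factor=1.3)
        assert an.birhythmicity_index(sp) == "birhythmic"  # generic rule fires
        assert not an.subharmonic_birhythmic(sp)  # period-doubling rule does not
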