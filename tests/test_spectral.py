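"""Spectral engine: R-peak detection, tachogram resampling, PSD, bands."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrvsurv import (
    BeatSeries,
    EcgTrace,
    SpectralIndices,
    SpectrumConfig,
    compute_indices,
    detect_r_peaks,
    integrate_band,
    psd_estimate,
    resample_tachogram,
    simulate_ecg,
)
from hrvsurv.exceptions import CoverageError, EmptySeriesError, InputError

CFG = SpectrumConfig()


def even_tachogram_with_sinusoids(components, base=800.0, cfg=CFG):
    t = np.arange(cfg.n_points) / cfg.sampling_rate
    x = np.full(cfg.n_points, base)
    for freq, amp in components:
        x = x + amp * np.sin(2 * np.pi * freq * t)
    return x


class TestBeatSeries:
    def test_ppi_and_times_must_agree(self):
        with pytest.raises(InputError):
            BeatSeries(np.array([0.0, 0.8, 1.6]), np.array([800.0, 900.0]))

    def test_from_ppi_roundtrip(self):
        ppi = np.array([700.0, 900.0, 800.0])
        b = BeatSeries.from_ppi(ppi)
        assert np.allclose(b.beat_times, [0.0, 0.7, 1.6, 2.4])
        assert np.allclose(BeatSeries.from_beat_times(b.beat_times).ppi, ppi)

    def test_nonpositive_ppi_rejected(self):
        with pytest.raises(InputError):
            BeatSeries.from_ppi(np.array([800.0, -50.0]))


class TestDetectRPeaks:
    def test_recovers_constructed_beat_schedule(self):
        schedule = np.arange(75) * 0.8  # 0.0, 0.8, ..., 59.2 s
        trace = simulate_ecg(BeatSeries.from_beat_times(schedule), 1024.0)
        beats = detect_r_peaks(trace)
        assert beats.n_beats == 75
        assert np.max(np.abs(beats.beat_times - schedule)) <= 2e-3

    def test_flat_trace_raises_empty_series(self):
        with pytest.raises(EmptySeriesError):
            detect_r_peaks(EcgTrace(np.zeros(4096), 1024.0))

    def test_nonfinite_samples_rejected(self):
        x = np.zeros(4096)
        x[10] = np.nan
        with pytest.raises(InputError):
            detect_r_peaks(EcgTrace(x, 1024.0))

    def test_alternating_intervals_recovered(self):
        times = np.concatenate([[0.0], np.cumsum(np.tile([0.7, 0.9], 40))])
        trace = simulate_ecg(BeatSeries.from_beat_times(times), 1024.0)
        beats = detect_r_peaks(trace)
        assert beats.n_beats == times.size
        assert np.allclose(beats.ppi[::2], 700.0, atol=2.0)
        assert np.allclose(beats.ppi[1::2], 900.0, atol=2.0)


class TestResampleTachogram:
    def test_constant_beats_give_constant_tachogram(self):
        beats = BeatSeries.from_ppi(np.full(380, 800.0))  # 304 s
        tach = resample_tachogram(beats, CFG)
        assert tach.shape == (2048,)
        assert np.max(np.abs(tach - 800.0)) < 1e-9

    def test_default_grid_covers_288_seconds_at_2048_points(self):
        beats = BeatSeries.from_ppi(np.full(380, 800.0))
        tach = resample_tachogram(beats, CFG)
        assert tach.size == CFG.n_points == 2048
        assert CFG.segment_seconds == 288.0
        assert CFG.sampling_rate == pytest.approx(2048 / 288)

    def test_short_recording_raises_coverage_error(self):
        beats = BeatSeries.from_ppi(np.full(100, 800.0))  # 80 s
        with pytest.raises(CoverageError):
            resample_tachogram(beats, CFG)

    def test_linear_ramp_matches_interpolation_oracle(self):
        # PPI ramps linearly 700 -> 900 ms against beat time, so any exact
        # interpolant must coincide with the straight line through the knots
        n = 400
        beat_times = [0.0]
        slope = 200.0 / 300.0  # ms per second
        for _ in range(n):
            ppi = 700.0 + slope * beat_times[-1]
            beat_times.append(beat_times[-1] + ppi / 1000.0)
        beats = BeatSeries.from_beat_times(np.array(beat_times))
        tach = resample_tachogram(beats, CFG)
        probes = np.linspace(0, 287.9, 20)
        oracle = np.interp(probes, beats.beat_times[:-1], beats.ppi)
        got = np.interp(probes, np.arange(2048) * 288 / 2048, tach)
        assert np.max(np.abs(got - oracle)) < 0.5  # ms, straight-line data


class TestPsdAndBands:
    def test_constant_tachogram_has_no_power(self):
        spectrum = psd_estimate(np.full(2048, 800.0), CFG)
        total = integrate_band(spectrum, (0.0, CFG.sampling_rate / 2))
        assert total < 1e-12

    @pytest.mark.parametrize("freq", [0.06, 0.1, 0.14, 0.2, 0.25, 0.3, 0.39])
    def test_sinusoid_total_power_matches_closed_form(self, freq):
        x = even_tachogram_with_sinusoids([(freq, 10.0)])
        spectrum = psd_estimate(x, CFG)
        total = integrate_band(spectrum, (0.0, CFG.sampling_rate / 2))
        assert total == pytest.approx(50.0, rel=0.02)

    def test_white_noise_mean_power_matches_variance(self):
        powers = []
        for seed in range(50):
            noise = 5.0 * np.random.default_rng(seed).standard_normal(2048)
            spectrum = psd_estimate(800.0 + noise, CFG)
            powers.append(integrate_band(spectrum, (0.0, CFG.sampling_rate / 2)))
        assert np.mean(powers) == pytest.approx(25.0, rel=0.05)

    def test_nonfinite_tachogram_rejected(self):
        x = np.full(2048, 800.0)
        x[7] = np.inf
        with pytest.raises(InputError):
            psd_estimate(x, CFG)

    def test_zero_density_integrates_to_zero(self):
        spectrum = psd_estimate(np.full(2048, 800.0), CFG)
        assert integrate_band(spectrum, CFG.hf_band) == pytest.approx(0.0, abs=1e-12)

    def test_inverted_band_rejected(self):
        spectrum = psd_estimate(np.full(2048, 800.0), CFG)
        with pytest.raises(InputError):
            integrate_band(spectrum, (0.4, 0.15))

    def test_hf_sinusoid_lands_in_hf_band_only(self):
        x = even_tachogram_with_sinusoids([(0.25, 10.0)])
        spectrum = psd_estimate(x, CFG)
        assert integrate_band(spectrum, CFG.hf_band) == pytest.approx(50.0, rel=0.02)
        assert integrate_band(spectrum, CFG.lf_band) < 1.0

    def test_two_sinusoids_split_between_bands(self):
        x = even_tachogram_with_sinusoids([(0.1, 8.0), (0.25, 10.0)])
        spectrum = psd_estimate(x, CFG)
        assert integrate_band(spectrum, CFG.lf_band) == pytest.approx(32.0, rel=0.02)
        assert integrate_band(spectrum, CFG.hf_band) == pytest.approx(50.0, rel=0.02)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_parseval_and_band_additivity(self, seed):
        g = np.random.default_rng(seed)
        x = 800.0 + 20.0 * g.standard_normal(2048)
        spectrum = psd_estimate(x, CFG)
        nyquist = CFG.sampling_rate / 2
        total = integrate_band(spectrum, (0.0, nyquist))
        assert total == pytest.approx(np.var(x), rel=0.01)
        parts = (
            integrate_band(spectrum, (0.0, 0.04))
            + integrate_band(spectrum, (0.04, 0.15))
            + integrate_band(spectrum, (0.15, 0.4))
        )
        whole = integrate_band(spectrum, (0.0, 0.4))
        assert parts == pytest.approx(whole, rel=1e-9)


class TestComputeIndices:
    def test_log_identities_on_band_powers(self):
        idx = SpectralIndices.from_band_powers(tp=100.0, lfp=20.0, hfp=math.e**2)
        assert idx.ln_hfp == pytest.approx(2.0)
        same = SpectralIndices.from_band_powers(tp=100.0, lfp=30.0, hfp=30.0)
        assert same.ln_lf_hf == pytest.approx(0.0)

    def test_zero_hfp_flags_ratio_undefined(self):
        beats = BeatSeries.from_ppi(np.full(380, 800.0))
        idx = compute_indices(beats, CFG)
        assert math.isnan(idx.lf_hf) and math.isnan(idx.ln_lf_hf)

    def test_hf_sinusoid_ln_hfp_near_closed_form(self):
        slope_free = []
        t = [0.0]
        while t[-1] < 300.0:
            ppi = 800.0 + 10.0 * math.sin(2 * math.pi * 0.25 * t[-1])
            slope_free.append(ppi)
            t.append(t[-1] + ppi / 1000.0)
        beats = BeatSeries(np.array(t), np.array(slope_free))
        idx = compute_indices(beats, CFG)
        assert idx.ln_hfp == pytest.approx(math.log(50.0), abs=0.05)
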