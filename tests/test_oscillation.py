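"""Oscillation pipeline: smoothing, cycle detection, periods, coupling."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from epimech.oscillation import (IntensityTrace, analyze_trace,
                                 autocorrelation, coupling_stats,
                                 cycle_amplitude, detect_cycles,
                                 period_from_intervals, preprocess,
                                 psd_dominant_period)
from epimech.synth import simulate_traces


def sinusoid(period_s=480.0, amplitude=1.0, dt_s=30.0, n=128, offset=0.0):
    t = np.arange(n) * dt_s
    return IntensityTrace(offset + amplitude * np.sin(2 * np.pi * t / period_s),
                          dt_s, label="sin")


class TestPreprocess:
    def test_constant_trace_shifts_by_background(self):
        trace = IntensityTrace(np.full(64, 30.0), 30.0)
        out = preprocess(trace, background_value=12.0)
        np.testing.assert_allclose(out.values, 18.0)

    def test_impulse_mass_is_preserved(self):
        x = np.zeros(64)
        x[32] = 10.0
        out = preprocess(IntensityTrace(x, 30.0), 0.0)
        assert out.values.sum() == pytest.approx(10.0)
        assert out.values.max() < 10.0

    def test_white_noise_variance_reduction_matches_kernel(self):
        # oracle: variance shrinks by the sum of squared kernel weights
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 20000)
        out = preprocess(IntensityTrace(x + 100, 1.0), 0.0)
        delta = np.zeros(61)
        delta[30] = 1.0
        weights = gaussian_filter1d(delta, 3.0, truncate=3.0)
        expected = float((weights ** 2).sum())
        assert out.values.var() / x.var() == pytest.approx(expected, rel=0.05)

    def test_linearity_after_zero_background(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(1, 2, 100)
        y = rng.uniform(1, 2, 100)
        lhs = preprocess(IntensityTrace(2 * x + 3 * y, 1.0), 0.0).values
        rhs = (2 * preprocess(IntensityTrace(x, 1.0), 0.0).values
               + 3 * preprocess(IntensityTrace(y, 1.0), 0.0).values)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            preprocess(IntensityTrace(np.ones(10), 1.0), 0.0)


class TestDetectCycles:
    def test_noiseless_sinusoid_yields_one_peak_per_period(self):
        trace = sinusoid(period_s=480.0, n=64)     # 4 periods
        cycles = detect_cycles(trace)
        assert cycles.n_peaks == 4
        assert not cycles.flagged
        assert abs(len(cycles.trough_indices) - 4) <= 1

    def test_monotone_ramp_is_flagged(self):
        cycles = detect_cycles(IntensityTrace(np.linspace(0, 1, 50), 1.0))
        assert cycles.flagged and cycles.n_peaks == 0

    def test_small_noise_preserves_peak_count(self):
        clean = sinusoid(n=128)
        rng = np.random.default_rng(3)
        noisy = IntensityTrace(
            clean.values + rng.normal(0, 0.01, 128), clean.dt_s)
        assert detect_cycles(noisy).n_peaks == detect_cycles(clean).n_peaks

    def test_peaks_and_troughs_alternate(self):
        trace = sinusoid(n=160)
        cycles = detect_cycles(trace)
        merged = sorted([(i, "p") for i in cycles.peak_indices]
                        + [(i, "t") for i in cycles.trough_indices])
        kinds = [k for _, k in merged]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))


class TestPeriodEstimators:
    def test_interval_mean_from_known_peaks(self):
        from epimech.oscillation import CycleSet
        cycles = CycleSet(np.array([4, 20, 36]), np.array([12, 28]),
                          np.array([1.0, 1.0]))
        summary = period_from_intervals(cycles, 30.0)
        np.testing.assert_allclose(summary.intervals_s, [480.0, 480.0])
        assert summary.mean_s == 480.0

    def test_irregular_intervals_average(self):
        from epimech.oscillation import CycleSet
        cycles = CycleSet(np.array([0, 10, 30]), np.array([5, 20]),
                          np.array([1.0, 1.0]))
        assert period_from_intervals(cycles, 1.0).mean_s == pytest.approx(15.0)

    def test_too_few_peaks_rejected(self):
        from epimech.oscillation import CycleSet
        with pytest.raises(ValueError):
            period_from_intervals(CycleSet(np.array([3]), np.array([]),
                                           np.array([])), 1.0)

    def test_on_bin_sinusoid_recovered_exactly(self):
        psd = psd_dominant_period(sinusoid(period_s=480.0, dt_s=30.0, n=128))
        assert psd.dominant_period_s == pytest.approx(480.0, rel=1e-12)

    def test_stronger_component_dominates_mixture(self):
        t = np.arange(256) * 30.0
        x = 3 * np.sin(2 * np.pi * t / 640) + 1 * np.sin(2 * np.pi * t / 240)
        # brute-force periodogram oracle over on-bin frequencies
        freqs = np.fft.rfftfreq(256, 30.0)[1:]
        powers = [np.abs(np.exp(-2j * np.pi * f * t) @ x) for f in freqs]
        oracle_period = 1.0 / freqs[int(np.argmax(powers))]
        psd = psd_dominant_period(IntensityTrace(x, 30.0))
        assert psd.dominant_period_s == pytest.approx(oracle_period)
        assert psd.dominant_period_s == pytest.approx(640.0)

    def test_estimators_agree_within_one_bin_on_bin_periods(self):
        n, dt = 256, 30.0
        for k in (8, 12, 16):                 # on-bin periods n*dt/k
            period = n * dt / k
            trace = sinusoid(period_s=period, dt_s=dt, n=n)
            psd = psd_dominant_period(trace).dominant_period_s
            cycles = detect_cycles(trace)
            ivl = period_from_intervals(cycles, dt).mean_s
            bin_width = period ** 2 / (n * dt)  # dT for one frequency bin
            assert abs(psd - ivl) <= bin_width + dt

    def test_autocorrelation_lag_zero_is_one(self):
        rng = np.random.default_rng(5)
        ac = autocorrelation(IntensityTrace(rng.uniform(0, 1, 64), 1.0))
        assert ac[0] == pytest.approx(1.0, rel=1e-12)

    def test_constant_trace_flagged(self):
        psd = psd_dominant_period(IntensityTrace(np.full(64, 3.0), 1.0))
        assert psd.flagged and np.isnan(psd.dominant_period_s)


class TestAmplitude:
    def test_sinusoid_amplitude_recovers_peak_to_peak(self):
        cycles = detect_cycles(sinusoid(amplitude=7.0, n=160))
        assert cycle_amplitude(cycles) == pytest.approx(14.0, rel=0.01)

    def test_constant_trace_has_no_cycles(self):
        cycles = detect_cycles(IntensityTrace(np.full(64, 2.0), 1.0))
        with pytest.raises(ValueError):
            cycle_amplitude(cycles)

    def test_generator_amplitude_recovered_within_ten_percent(self, config):
        errs = []
        for seed in range(10):
            b = simulate_traces(config, "control", 7680, seed=seed,
                                noise_frac=0.05)
            res = analyze_trace(b.myosin)
            errs.append(abs(res["amplitude"] - 2 * b.truth_amplitude)
                        / (2 * b.truth_amplitude))
        assert np.mean(errs) < 0.10


class TestCoupling:
    def test_in_phase_pair_correlates_perfectly(self, noiseless_config):
        b = simulate_traces(noiseless_config, "control", 3600, seed=1,
                            noise_frac=0.0)
        stats = coupling_stats(b)
        assert stats.r_myosin_protrusion == pytest.approx(1.0, abs=1e-9)
        assert stats.r_myosin_area == pytest.approx(-1.0, abs=1e-9)
        assert stats.lag_myosin_protrusion_s == 0.0

    def test_constant_trace_flags_result(self):
        class Bundle:
            myosin = IntensityTrace(np.full(64, 5.0), 30.0, "myosin")
            protrusion_pct = IntensityTrace(np.full(64, 5.0), 30.0, "p")
            basal_area = IntensityTrace(np.full(64, 5.0), 30.0, "a")
        assert coupling_stats(Bundle()).flagged

    def test_noisy_in_phase_coupling_stays_strong(self, config):
        rs = []
        for seed in range(20):
            b = simulate_traces(config, "mutant", 3600, seed=seed,
                                noise_frac=0.10)
            rs.append(coupling_stats(b).r_myosin_protrusion)
        assert np.mean(rs) > 0.8
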