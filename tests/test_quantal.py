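import numpy as np
import pytest
from dataclasses import replace
from scipy.signal import fftconvolve

from retinfo import quantal, synth
from retinfo.quantal import (
    DeconvolutionKernel,
    EventSeries,
    LinescanRecording,
    QuantalSeries,
    SpatialComponent,
    cluster_quanta,
    compute_dff,
    detect_events,
    extract_timeseries,
    fit_spatial_components,
    quanta_per_cycle,
    release_rate,
    wiener_deconvolve,
)


def _profile_recording(profile, n_lines=200):
    return LinescanRecording(
        np.tile(np.asarray(profile, float)[:, None], (1, n_lines)), dt=0.001, dx=0.25
    )


class TestSpatialComponents:
    x = np.arange(48) * 0.25

    def test_single_gaussian_exact(self):
        prof = 2.0 * np.exp(-0.5 * ((self.x - 10.0) / 1.5) ** 2)
        comps = fit_spatial_components(_profile_recording(prof))
        assert len(comps) == 1
        assert abs(comps[0].center - 10.0) < 0.1
        assert comps[0].width == pytest.approx(1.5, abs=0.1)

    def test_two_gaussians_resolved(self):
        # oracle: RSS scan over k = 1..4 on the noiseless profile picks k = 2
        prof = np.exp(-0.5 * ((self.x - 2.0) / 1.2) ** 2) + np.exp(
            -0.5 * ((self.x - 10.0) / 1.2) ** 2
        )
        comps = fit_spatial_components(_profile_recording(prof))
        assert len(comps) == 2
        assert abs(comps[0].center - 2.0) < 0.2
        assert abs(comps[1].center - 10.0) < 0.2

    def test_uniform_profile_no_components(self):
        assert fit_spatial_components(_profile_recording(np.full(48, 5.0))) == []

    def test_too_few_pixels(self):
        rec = LinescanRecording(np.ones((8, 100)), dt=0.001, dx=0.25)
        with pytest.raises(ValueError):
            fit_spatial_components(rec)


class TestExtractTimeseries:
    def test_single_component_proportional(self):
        comp = SpatialComponent(center=6.0, width=1.2, amplitude=1.0)
        x = np.arange(48) * 0.25
        amp = 100 + 10 * np.sin(np.arange(300) / 20)
        values = comp.profile(x, unit_peak=True)[:, None] * amp[None, :]
        rec = LinescanRecording(values, 0.001, 0.25)
        traces = extract_timeseries(rec, [comp])
        assert np.allclose(traces[0], amp, rtol=1e-10)

    def test_two_components_recovered_within_2pct(self):
        # oracle: per-pixel averaging over each component's +/-2 sigma window
        x = np.arange(64) * 0.25
        c1 = SpatialComponent(center=4.0, width=1.0, amplitude=1.0)
        c2 = SpatialComponent(center=12.0, width=1.0, amplitude=1.0)
        t = np.arange(500)
        a1 = 100 + 50 * np.exp(-(((t - 100) / 30.0) ** 2))
        a2 = 100 + 80 * np.exp(-(((t - 350) / 30.0) ** 2))
        values = (
            c1.profile(x, unit_peak=True)[:, None] * a1[None, :]
            + c2.profile(x, unit_peak=True)[:, None] * a2[None, :]
        )
        rec = LinescanRecording(values, 0.001, 0.25)
        traces = extract_timeseries(rec, [c1, c2])
        assert np.abs(traces[0] / a1 - 1).max() < 0.02
        assert np.abs(traces[1] / a2 - 1).max() < 0.02
        # reconstruction explains the spatially integrated signal
        recon = (
            c1.profile(x, unit_peak=True)[:, None] * traces[0]
            + c2.profile(x, unit_peak=True)[:, None] * traces[1]
        )
        ss_res = np.sum((values - recon) ** 2)
        ss_tot = np.sum((values - values.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.95

    def test_coincident_components_merged_with_warning(self):
        x = np.arange(48) * 0.25
        c1 = SpatialComponent(center=6.0, width=1.2, amplitude=1.0)
        c2 = SpatialComponent(center=6.001, width=1.2, amplitude=1.0)
        values = c1.profile(x, unit_peak=True)[:, None] * np.full(100, 50.0)[None, :]
        rec = LinescanRecording(values, 0.001, 0.25)
        with pytest.warns(UserWarning):
            traces = extract_timeseries(rec, [c1, c2])
        assert traces.shape[0] == 1


class TestComputeDff:
    def test_constant_trace_zeroes(self):
        d = compute_dff(np.full(500, 7.0), bleach_correction=False)
        assert np.allclose(d, 0.0)

    def test_mode_dominates_excursions(self):
        tr = np.full(1000, 100.0)
        tr[100:180] = 200.0
        d = compute_dff(tr, bleach_correction=False)
        assert d[150] == pytest.approx(1.0, abs=1e-6)
        assert abs(d[500]) < 1e-6

    def test_bleach_corrected_slope_small(self):
        rng = np.random.default_rng(2)
        t = np.arange(60_000) * 0.001
        tr = 100 * np.exp(-t / 300.0) + rng.normal(0, 0.5, t.size)
        d = compute_dff(tr, 0.001, bleach_correction=True)
        drift = abs(np.polyfit(t, d, 1)[0]) * t[-1]
        assert drift < 0.01  # < 1% of F0 over the recording

    def test_negative_baseline_rejected(self):
        with pytest.raises(ValueError):
            compute_dff(np.full(500, -5.0), bleach_correction=False)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            compute_dff(np.ones(50))


class TestWienerDeconvolve:
    def test_inverse_filter_limit_single_impulse(self, kernel):
        h = kernel.sample(0.001)
        y = fftconvolve(np.eye(1, 3000, 1000)[0] * 0.7, h)[:3000]
        x = wiener_deconvolve(y, kernel, 0.001, snr_param=1e9)
        assert np.argmax(x) == 1000
        assert x.max() == pytest.approx(0.7, rel=0.01)

    def test_amplitude_ratio_two_transients(self, kernel):
        h = kernel.sample(0.001)
        imp = np.zeros(3000)
        imp[500], imp[600] = 1.0, 2.0
        y = fftconvolve(imp, h)[:3000]
        x = wiener_deconvolve(y, kernel, 0.001, snr_param=1e9)
        ev = detect_events(x, 0.001, amplitude_mode="peak")
        top = np.sort(ev.amplitudes)[-2:]
        assert top[1] / top[0] == pytest.approx(2.0, rel=0.05)

    def test_linearity_with_fixed_filter(self, kernel):
        h = kernel.sample(0.001)
        y1 = fftconvolve(np.eye(1, 2000, 400)[0], h)[:2000]
        y2 = fftconvolve(np.eye(1, 2000, 900)[0] * 2, h)[:2000]
        xs = wiener_deconvolve(y1 + y2, kernel, 0.001, snr_param=100.0)
        x1 = wiener_deconvolve(y1, kernel, 0.001, snr_param=100.0)
        x2 = wiener_deconvolve(y2, kernel, 0.001, snr_param=100.0)
        assert np.abs(xs - (x1 + x2)).max() < 1e-10

    def test_invalid_snr(self, kernel):
        with pytest.raises(ValueError):
            wiener_deconvolve(np.zeros(1000), kernel, 0.001, snr_param=0.0)

    def test_kernel_validation(self):
        with pytest.raises(ValueError):
            DeconvolutionKernel(tau_r=0.1, tau_f=0.05)


class TestDetectEvents:
    def test_pure_noise_few_events(self):
        # oracle: Gaussian tail probability at 4 SD x 1e4 samples ~ 0.3
        rng = np.random.default_rng(0)
        counts = [
            len(detect_events(rng.normal(0, 1, 10_000), 0.001, k_sd=4.0))
            for _ in range(20)
        ]
        assert np.mean(counts) <= 2.0

    def test_single_large_impulse(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 5000)
        x[2500] += 10.0
        ev = detect_events(x, 0.001, k_sd=4.0)
        big = np.argmax(ev.amplitudes)
        assert ev.times[big] == pytest.approx(2.5, abs=0.001)

    def test_event_count_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 0.1, 20_000)
        x[::500] += rng.uniform(0.2, 1.0, 40)
        counts = [len(detect_events(x, 0.001, k_sd=k)) for k in (2.0, 3.0, 4.0, 5.0, 6.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_k_sd_bounds(self):
        with pytest.raises(ValueError):
            detect_events(np.zeros(100), k_sd=1.0)


class TestClusterQuanta:
    def test_exact_multiples_with_given_quantal_size(self):
        ev = EventSeries(np.arange(4.0), np.array([0.20, 0.41, 0.60, 0.19]))
        series = cluster_quanta(ev, quantal_size=0.20)
        assert list(series.quanta) == [1, 2, 3, 1]

    def test_parameter_recovery_on_simulated_amplitudes(self):
        rng = np.random.default_rng(1)
        ks = rng.choice([1, 2, 3], 500, p=[0.6, 0.3, 0.1])
        amps = ks * 0.25 * (1 + 0.10 * rng.normal(size=500))
        series = cluster_quanta(EventSeries(np.arange(500.0), amps), seed=0)
        assert abs(series.quantal_size - 0.25) / 0.25 < 0.05
        assert np.mean(series.quanta == ks) > 0.9

    def test_single_amplitude_population(self):
        amps = np.full(50, 0.3)
        series = cluster_quanta(EventSeries(np.arange(50.0), amps), seed=0)
        assert np.all(series.quanta == 1)
        assert series.quantal_size == pytest.approx(0.3, rel=1e-3)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        ks = rng.choice([1, 2, 3], 300, p=[0.5, 0.3, 0.2])
        amps = ks * 0.4 * (1 + 0.08 * rng.normal(size=300))
        a = cluster_quanta(EventSeries(np.arange(300.0), amps), seed=1)
        b = cluster_quanta(EventSeries(np.arange(300.0), 3.0 * amps), seed=1)
        assert b.quantal_size / a.quantal_size == pytest.approx(3.0, rel=1e-6)
        assert np.array_equal(a.quanta, b.quanta)

    def test_too_few_events_requires_quantal_size(self):
        ev = EventSeries(np.arange(5.0), np.full(5, 0.2))
        with pytest.raises(ValueError):
            cluster_quanta(ev)


class TestRates:
    def test_release_rate_arithmetic(self):
        series = QuantalSeries(
            np.linspace(0.1, 9.9, 18), np.full(18, 2), quantal_size=0.2
        )
        assert release_rate(series, (0.0, 10.0)) == pytest.approx(3.6)

    def test_empty_series_zero_rate(self):
        series = QuantalSeries(np.empty(0), np.empty(0, int), 1.0)
        assert release_rate(series, (0.0, 5.0)) == 0.0

    def test_quanta_per_cycle_counts(self):
        series = QuantalSeries(np.array([0.05, 0.25, 0.45]), np.array([2, 1, 3]), 0.2)
        counts, mean = quanta_per_cycle(series, 5.0, 0.6, phase_window=None)
        assert list(counts) == [2, 1, 3]
        assert mean == 2.0


class TestPipelineRecovery:
    def test_noise_free_roundtrip_exact(self, kernel, component, cohort):
        # noiseless rendering + decomposition returns the ground-truth quanta
        reg = replace(
            cohort["pm"].synapse,
            noise_sd=0.0,
            spont_rate=0.0,
            evoked_max=2.0,
            phase_jitter_sd=0.030,
        )
        from retinfo.regimes import StimulusProtocol

        proto = StimulusProtocol.constant(100.0, 10.0)
        train = synth.simulate_release(reg, proto, 21)
        rec = synth.render_linescan(train, [component], kernel, reg, seed=0)
        series, _ = quantal.decompose_recording(rec, kernel, snr_param=1e7)
        assert series.total_quanta == train.total_quanta

    def test_snr5_recall_and_quantal_accuracy(self, decomposed_pm):
        # at quantal SNR 5: >= 90% of ground-truth events near a detected
        # event, and total quanta within 15% of truth
        recall_n = recall_d = 0
        est_q = true_q = 0
        for train, rec, series, _ in decomposed_pm:
            det = series.times
            for t in train.event_times:
                recall_d += 1
                if det.size and np.min(np.abs(det - t)) < 0.020:
                    recall_n += 1
            est_q += series.total_quanta
            true_q += train.total_quanta
        assert recall_n / recall_d >= 0.9
        assert abs(est_q / true_q - 1) < 0.15

    def test_quantal_size_recovered(self, decomposed_pm, cohort):
        qs = [series.quantal_size for _, _, series, _ in decomposed_pm]
        assert np.mean(qs) == pytest.approx(
            cohort["pm"].synapse.quantal_dff, rel=0.10
        )
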