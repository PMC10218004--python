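"""Evoked-response model: convolution, 1/f noise, TRF estimation, ensembles."""

import numpy as np
import pytest
from scipy import signal as sps

from edgetrack.containers import EventInputSeries, Kernel, LandmarkEvents, NoiseConfig, ResponseSeries
from edgetrack.evoked import (
    add_pink_noise,
    convolve_kernel,
    ensemble_grid,
    estimate_trf,
    pink_noise,
    run_randomized_ensemble,
)
from edgetrack.synth import EventTrainSpec, generate_event_train, generate_synthetic_response

FS = 400.0


def _impulse_input(times, mags, duration):
    s = np.zeros(int(duration * FS))
    for t, m in zip(times, mags):
        s[int(round(t * FS))] += m
    return EventInputSeries(s=s, fs=FS)


class TestConvolution:
    def test_single_unit_event_places_kernel(self, kernel):
        inp = _impulse_input([2.0], [1.0], 4.0)
        out = convolve_kernel(inp, kernel).channel()
        start = int(round(2.0 * FS)) + int(round(kernel.lag_window[0] * FS))
        np.testing.assert_allclose(
            out[start : start + kernel.values.size], kernel.values, atol=1e-14
        )

    def test_superposition(self, kernel):
        a = convolve_kernel(_impulse_input([1.0], [0.4], 6.0), kernel).channel()
        b = convolve_kernel(_impulse_input([4.0], [0.7], 6.0), kernel).channel()
        both = convolve_kernel(
            _impulse_input([1.0, 4.0], [0.4, 0.7], 6.0), kernel
        ).channel()
        np.testing.assert_allclose(both, a + b, atol=1e-14)

    def test_periodic_train_spectrum_has_rate_harmonics(self, kernel):
        rate, dur = 1.9, 100.0
        times = np.arange(0.5, dur - 1.0, 1 / rate)
        out = convolve_kernel(
            _impulse_input(times, np.ones(times.size), dur), kernel
        ).channel()
        freqs = np.fft.rfftfreq(out.size, 1 / FS)
        mag = np.abs(np.fft.rfft(out))
        # energy concentrates on lines at multiples of the event rate
        for harmonic in (1.9, 3.8, 5.7):
            i = np.argmin(np.abs(freqs - harmonic))
            window = mag[max(i - 40, 0) : i + 40]
            assert mag[i - 2 : i + 3].max() == window.max()

    def test_fs_mismatch_rejected(self, kernel):
        inp = EventInputSeries(s=np.zeros(100), fs=200.0)
        with pytest.raises(ValueError, match="fs mismatch"):
            convolve_kernel(inp, kernel)


class TestPinkNoise:
    def test_unit_rms(self):
        x = pink_noise(50000, FS, seed=1)
        assert np.sqrt(np.mean(x**2)) == pytest.approx(1.0, abs=1e-9)

    def test_loglog_magnitude_slope_near_minus_one(self):
        x = pink_noise(200000, FS, seed=2)
        f, P = sps.welch(x, fs=FS, nperseg=16384)
        band = (f > 0.5) & (f < 40)
        slope = np.polyfit(np.log10(f[band]), np.log10(np.sqrt(P[band])), 1)[0]
        assert abs(slope + 1.0) < 0.1

    def test_amplitude_snr_realized_within_two_percent(self):
        rng = np.random.default_rng(3)
        x = np.sin(2 * np.pi * 3.0 * np.arange(80000) / FS)
        resp = ResponseSeries(data=x, fs=FS)
        noisy = add_pink_noise(
            resp, NoiseConfig(snr=0.1, snr_domain="amplitude"), rng=rng
        )
        noise_part = noisy.channel() - x
        realized = np.sqrt(np.mean(x**2)) / np.sqrt(np.mean(noise_part**2))
        assert abs(realized - 0.1) / 0.1 < 0.02

    def test_power_snr_uses_sqrt_scaling(self):
        rng = np.random.default_rng(4)
        x = np.sin(2 * np.pi * 3.0 * np.arange(80000) / FS)
        resp = ResponseSeries(data=x, fs=FS)
        noisy = add_pink_noise(resp, NoiseConfig(snr=0.1, snr_domain="power"), rng=rng)
        noise_part = noisy.channel() - x
        power_ratio = np.mean(x**2) / np.mean(noise_part**2)
        assert abs(power_ratio - 0.1) / 0.1 < 0.05

    def test_huge_snr_leaves_signal_untouched(self):
        x = np.sin(2 * np.pi * 3.0 * np.arange(8000) / FS)
        resp = ResponseSeries(data=x, fs=FS)
        noisy = add_pink_noise(resp, NoiseConfig(snr=1e6, snr_domain="amplitude"))
        rel = np.sqrt(np.mean((noisy.channel() - x) ** 2) / np.mean(x**2))
        assert rel < 1e-3

    def test_ensemble_mean_converges_like_sqrt_n(self, kernel):
        """Averaging noisy responses shrinks the noise as 1/sqrt(n)."""
        inp = _impulse_input([1.0, 2.0, 3.0], [1.0, 0.8, 0.6], 5.0)
        clean = convolve_kernel(inp, kernel)
        rng = np.random.default_rng(5)
        cfg = NoiseConfig(snr=1.0, snr_domain="amplitude")

        def mean_err(n):
            acc = np.zeros(clean.n_samples)
            for _ in range(n):
                acc += add_pink_noise(clean, cfg, rng=rng).channel()
            return np.sqrt(np.mean((acc / n - clean.channel()) ** 2))

        ratio = mean_err(25) / mean_err(100)
        assert 1.4 < ratio < 2.9  # expect ~2


class TestTRF:
    def test_exact_recovery_without_noise(self, kernel, regular_train):
        from edgetrack.oscillator import build_event_input

        stim = build_event_input(regular_train, fs=FS, duration=62.0)
        resp = convolve_kernel(stim, kernel)
        est = estimate_trf(stim, resp, ridge=0.0)
        assert np.sqrt(np.mean((est.values - kernel.values) ** 2)) < 1e-6

    def test_recovery_degrades_monotonically_with_noise(self, kernel, regular_train):
        corrs = []
        for i, snr in enumerate((10.0, 1.0, 0.1)):
            cfg = NoiseConfig(snr=snr, snr_domain="amplitude", jitter_sd=0.0)
            sim = generate_synthetic_response(
                regular_train, kernel, cfg, fs=FS, seed=20 + i
            )
            est = estimate_trf(sim.stimulus, sim.response)
            corrs.append(np.corrcoef(est.values, kernel.values)[0, 1])
        assert corrs[0] >= corrs[1] >= corrs[2]
        assert corrs[0] > 0.99

    def test_ridge_shrinks_pure_noise_kernel(self, regular_train):
        from edgetrack.oscillator import build_event_input

        rng = np.random.default_rng(6)
        stim = build_event_input(regular_train, fs=FS, duration=62.0)
        resp = ResponseSeries(data=rng.standard_normal(stim.n_samples), fs=FS)
        norms = [
            np.linalg.norm(estimate_trf(stim, resp, ridge=lam).values)
            for lam in (1e-4, 1e-1, 1e2)
        ]
        assert norms[0] > norms[1] > norms[2]

    def test_rank_deficient_design_raises_without_ridge(self):
        stim = EventInputSeries(s=np.zeros(2000), fs=FS)
        resp = ResponseSeries(data=np.zeros(2000), fs=FS)
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            estimate_trf(stim, resp, ridge=0.0)


class TestEnsemble:
    def test_grid_size_default_is_2560(self):
        assert len(ensemble_grid(NoiseConfig())) == 64 * 40

    def test_single_iteration_returns_single_output(self, kernel):
        events = LandmarkEvents(times=np.array([1.0]), magnitudes=np.array([1.0]))
        cfg = NoiseConfig(snr=1e6, jitter_sd=0.0, n_temporal_iters=1, n_amplitude_iters=1)
        out = run_randomized_ensemble(
            events, kernel, cfg, lambda r: r.channel().copy(), fs=FS, duration=2.0
        )
        expected = convolve_kernel(
            _impulse_input([1.0], [1.0], 2.0), kernel
        ).channel()
        np.testing.assert_allclose(out, expected, atol=1e-3)

    def test_deterministic_given_seed(self, kernel, regular_train):
        cfg = NoiseConfig(snr=0.5, jitter_sd=0.01, n_temporal_iters=2, n_amplitude_iters=2, seed=7)
        call = lambda: run_randomized_ensemble(  # noqa: E731
            regular_train, kernel, cfg, lambda r: float(np.mean(r.channel() ** 2)), fs=FS
        )
        assert call() == call()

    def test_callback_outputs_averaged_over_grid(self, kernel):
        events = LandmarkEvents(times=np.array([1.0]), magnitudes=np.array([1.0]))
        cfg = NoiseConfig(snr=1.0, jitter_sd=0.0, n_temporal_iters=3, n_amplitude_iters=4, seed=1)
        count = []
        out = run_randomized_ensemble(
            events, kernel, cfg,
            lambda r: (count.append(1), np.asarray(1.0))[1],
            fs=FS, duration=2.0,
        )
        assert len(count) == 12
        assert out == pytest.approx(1.0)
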