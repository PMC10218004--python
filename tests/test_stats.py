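"""Phase statistics: IEPC, CAC, cluster tests, profiles, quantiles, ERP."""

import numpy as np
import pytest

from edgetrack.containers import BandSpec, EpochedPhases, LandmarkEvents, ResponseSeries
from edgetrack.stats import (
    cac,
    cluster_perm_test,
    compare_alignments,
    compare_models,
    erp_average,
    find_profile_peaks,
    iepc,
    noise_robustness_sweep,
    quantile_iepc,
    spectral_profile,
    temporal_profile,
    theoretical_baseline,
    IEPCMap,
)
from edgetrack.tf import make_band_spec, tf_decompose

FS = 400.0


def _epochs(phase, fs=FS, window=(-0.5, 0.5)):
    phase = np.asarray(phase, float)
    spec = BandSpec(centers=2.0 ** np.arange(phase.shape[1]), half_width=0.1)
    return EpochedPhases(phase=phase, window=window, fs=fs, band_spec=spec)


class TestIEPC:
    def test_identical_epochs_give_unity(self, rng):
        one = rng.uniform(-np.pi, np.pi, size=(1, 2, 50))
        ep = _epochs(np.repeat(one, 20, axis=0))
        np.testing.assert_allclose(iepc(ep).values, 1.0, atol=1e-12)

    def test_balanced_phases_cancel(self):
        n = 8
        phase = np.tile(
            (2 * np.pi * np.arange(n) / n)[:, None, None], (1, 2, 10)
        )
        assert np.max(iepc(_epochs(phase)).values) < 1e-12

    def test_matches_direct_complex_sum(self, rng):
        phase = rng.uniform(-np.pi, np.pi, size=(7, 2, 4))
        expected = np.abs(np.exp(1j * phase).sum(axis=0)) / 7
        np.testing.assert_allclose(iepc(_epochs(phase)).values, expected, atol=1e-12)

    def test_uniform_phases_match_monte_carlo_expectation(self, rng):
        n_events, n_rep = 100, 400
        vals = [
            iepc(_epochs(rng.uniform(-np.pi, np.pi, size=(n_events, 1, 1)))).values.item()
            for _ in range(n_rep)
        ]
        mc = theoretical_baseline(n_events, n_mc=20000, seed=1)
        se = np.std(vals, ddof=1) / np.sqrt(n_rep)
        assert abs(np.mean(vals) - mc) < 2 * se + 0.003

    def test_global_rotation_invariance(self, rng):
        phase = rng.uniform(-np.pi, np.pi, size=(12, 3, 8))
        rotated = np.angle(np.exp(1j * (phase + 1.234)))
        np.testing.assert_allclose(
            iepc(_epochs(phase)).values, iepc(_epochs(rotated)).values, atol=1e-12
        )

    def test_fewer_than_two_events_rejected(self, rng):
        with pytest.raises(ValueError):
            iepc(_epochs(rng.uniform(-np.pi, np.pi, size=(1, 2, 4))))


class TestTheoreticalBaseline:
    def test_two_angles_match_quadrature(self):
        # resultant of two unit phasors is |cos(delta/2)|; uniform delta
        # integrates to 2/pi
        mc = theoretical_baseline(2, n_mc=400000, seed=0)
        assert abs(mc - 2 / np.pi) < 0.002

    def test_decreasing_in_event_count(self):
        values = [theoretical_baseline(n, n_mc=20000, seed=1) for n in (10, 100, 1000)]
        assert values[0] > values[1] > values[2]

    def test_reproducible_for_fixed_seed(self):
        assert theoretical_baseline(50, seed=3) == theoretical_baseline(50, seed=3)


class TestCAC:
    def _maps(self, phase_a, phase_b, fs=FS):
        spec = BandSpec(centers=np.array([1.0, 2.0]), half_width=0.5)
        from edgetrack.containers import TFPhaseMap

        mk = lambda p: TFPhaseMap(  # noqa: E731
            phase=p, amplitude=np.ones_like(p), fs=fs, band_spec=spec
        )
        return mk(phase_a), mk(phase_b)

    def test_identical_phases_give_unity(self, rng):
        p = rng.uniform(-np.pi, np.pi, size=(2, 8000))
        a, b = self._maps(p, p.copy())
        np.testing.assert_allclose(cac(a, b, [(0, 20.0)]).values, 1.0, atol=1e-12)

    def test_constant_offset_gives_unity(self, rng):
        p = rng.uniform(-np.pi, np.pi, size=(2, 8000))
        a, b = self._maps(p, np.angle(np.exp(1j * (p + 0.9))))
        np.testing.assert_allclose(cac(a, b, [(0, 20.0)]).values, 1.0, atol=1e-12)

    def test_independent_phases_match_uniform_null(self, rng):
        n = 4000  # samples per utterance
        vals = []
        for _ in range(40):
            a, b = self._maps(
                rng.uniform(-np.pi, np.pi, size=(2, n)),
                rng.uniform(-np.pi, np.pi, size=(2, n)),
            )
            vals.append(cac(a, b, [(0, n / FS)]).values)
        null = theoretical_baseline(n, n_mc=4000, seed=2)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - null) < 3 * se + 0.003

    def test_slow_split_averages_thirds(self, rng):
        p = rng.uniform(-np.pi, np.pi, size=(2, 9000))
        a, b = self._maps(p, p.copy())
        out = cac(a, b, [(0, 22.5)], slow_split=3)
        np.testing.assert_allclose(out.values, 1.0, atol=1e-12)

    def test_short_utterance_warns(self, rng):
        p = rng.uniform(-np.pi, np.pi, size=(2, 4000))
        a, b = self._maps(p, p.copy())
        with pytest.warns(UserWarning, match="shorter than one cycle"):
            cac(a, b, [(0.0, 0.2)])


class TestClusterTest:
    def test_constant_maps_have_no_clusters(self):
        maps = np.full((8, 5, 60), 0.3)
        times = -0.5 + np.arange(60) / 60
        res = cluster_perm_test(maps, times, n_perm=200, seed=0)
        assert len(res.p_values) == 0

    def test_injected_elevation_detected_in_right_place(self, rng):
        maps = rng.uniform(0.0, 0.1, size=(10, 10, 120))
        times = -0.5 + np.arange(120) / 120
        maps[:, 3:6, 70:100] += 0.25
        res = cluster_perm_test(maps, times, n_perm=400, seed=1)
        sig = res.significant(0.01)
        assert len(sig) >= 1
        assert sig[0][4, 85]
        covered = np.flatnonzero(sig[0].any(axis=1))
        assert set(covered) <= set(range(2, 7))

    def test_too_few_replicates_rejected(self, rng):
        maps = rng.uniform(size=(3, 4, 50))
        with pytest.raises(ValueError):
            cluster_perm_test(maps, np.linspace(-0.5, 0.5, 50))

    def test_family_wise_error_controlled(self, rng):
        """Null simulations: significant-cluster rate stays near cluster alpha."""
        alpha, n_sim = 0.05, 80
        times = np.linspace(-0.5, 0.5, 40)
        hits = 0
        for i in range(n_sim):
            maps = rng.uniform(0.0, 0.2, size=(8, 8, 40))
            res = cluster_perm_test(
                maps, times, n_perm=250, peak_alpha=0.05, cluster_alpha=alpha, seed=i
            )
            if any(p < alpha for p in res.p_values):
                hits += 1
        # binomial 99% upper bound around alpha
        bound = alpha + 2.6 * np.sqrt(alpha * (1 - alpha) / n_sim)
        assert hits / n_sim <= bound


class TestProfiles:
    def _map(self, values, centers=None, window=(-0.5, 0.5)):
        values = np.asarray(values, float)
        if centers is None:
            centers = 2.0 ** np.linspace(0, 3, values.shape[0])
        spec = BandSpec(centers=np.asarray(centers), half_width=0.1)
        return IEPCMap(
            values=values, band_spec=spec, window=window, fs=FS, n_events=50
        )

    def test_profile_is_windowed_time_average(self):
        n_t = int(FS) + 1
        values = np.tile(np.linspace(0, 1, n_t), (4, 1))
        m = self._map(values)
        profile, baseline = spectral_profile(m, "slow")
        w = m.time_mask((0.0, 0.5))
        np.testing.assert_allclose(profile, values[:, w].mean(axis=1))
        b = m.time_mask((-0.4, -0.1))
        np.testing.assert_allclose(baseline, values[:, b].mean(axis=1))

    def test_unknown_condition_rejected(self):
        m = self._map(np.zeros((4, int(FS) + 1)))
        with pytest.raises(ValueError):
            spectral_profile(m, "warp")

    def test_flat_profile_has_no_peaks(self):
        assert find_profile_peaks(np.full(20, 0.3), np.zeros(20), 0.0).size == 0

    def test_two_bumps_found_and_edges_ignored(self):
        x = np.linspace(0, 1, 30)
        profile = (
            0.3 * np.exp(-((x - 0.25) ** 2) / 0.004)
            + 0.4 * np.exp(-((x - 0.7) ** 2) / 0.004)
            + 0.05
        )
        peaks = find_profile_peaks(profile, np.zeros(30), 0.0)
        assert peaks.size == 2

    def test_temporal_profile_band_selection_and_chance(self):
        n_t = int(1.5 * FS) + 1
        centers = 0.67 * 2 ** (0.1 * np.arange(38))
        values = np.full((38, n_t), 0.05)
        sel = (centers >= 1.9 * 2**-0.25) & (centers <= 1.9 * 2**0.25)
        values[sel, :] = 0.8
        m = self._map(values, centers=centers, window=(-0.5, 1.0))
        out = temporal_profile(m, center=1.9, seed=0)
        np.testing.assert_allclose(out["values"], 0.8)
        assert out["baseline"] == pytest.approx(
            theoretical_baseline(50, n_mc=2000, seed=0), abs=1e-12
        )
        assert out["exceeds"].all()


class TestCompareModels:
    def test_observed_equals_one_model(self, rng):
        er = rng.standard_normal(30)
        osc = rng.standard_normal(30)
        out = compare_models(er[None, :], {"osc": osc, "er": er})
        assert out["correlations"]["er"][0] == pytest.approx(1.0)
        assert out["betas"]["er"][0] == pytest.approx(1.0, abs=1e-9)
        assert out["betas"]["osc"][0] == pytest.approx(0.0, abs=1e-9)

    def test_pure_noise_correlations_centered_on_zero(self, rng):
        er = rng.standard_normal(40)
        osc = rng.standard_normal(40)
        obs = rng.standard_normal((200, 40))
        out = compare_models(obs, {"osc": osc, "er": er})
        for k in ("osc", "er"):
            assert abs(np.nanmean(out["correlations"][k])) < 0.05

    def test_mixture_weights_recovered(self, rng):
        er = rng.standard_normal(60)
        osc = rng.standard_normal(60)
        obs = np.stack(
            [0.7 * er + 0.3 * osc + 0.01 * rng.standard_normal(60) for _ in range(12)]
        )
        out = compare_models(obs, {"osc": osc, "er": er})
        assert abs(out["betas"]["er"].mean() - 0.7) < 0.07
        assert abs(out["betas"]["osc"].mean() - 0.3) < 0.03
        assert out["beta_p"]["er"] < 1e-6

    def test_degenerate_profile_reports_nan(self):
        out = compare_models(
            np.zeros((1, 10)), {"er": np.arange(10.0), "osc": np.ones(10)}
        )
        assert np.isnan(out["correlations"]["er"][0])


class TestQuantileIEPC:
    def _graded_epochs(self, rng, n=150, kappa_hi=40.0):
        """Phase concentration grows with event magnitude (construction oracle)."""
        mags = rng.uniform(0.05, 1.0, size=n)
        sigma = 1.8 * (1.05 - mags)  # monotone: bigger edge -> tighter phase
        phase = rng.normal(0.0, sigma[:, None, None], size=(n, 3, 81))
        spec = BandSpec(centers=np.array([4.5, 5.7, 7.2]), half_width=0.1)
        ep = EpochedPhases(
            phase=np.angle(np.exp(1j * phase)),
            window=(-0.1, 0.1),
            fs=FS,
            band_spec=spec,
        )
        return ep, mags

    def test_iepc_increases_across_magnitude_quantiles(self, rng):
        from scipy.stats import spearmanr

        ep, mags = self._graded_epochs(rng)
        res = quantile_iepc(ep, mags, band=(4, 8))
        rho = spearmanr(np.arange(5), res.values).statistic
        assert rho == pytest.approx(1.0)
        assert res.boundaries.size == 6
        assert np.all(np.diff(res.boundaries) >= 0)

    def test_equal_magnitudes_give_equal_quantiles(self, rng):
        n = 200
        phase = rng.normal(0.0, 0.5, size=(n, 3, 81))
        spec = BandSpec(centers=np.array([4.5, 5.7, 7.2]), half_width=0.1)
        ep = EpochedPhases(
            phase=np.angle(np.exp(1j * phase)), window=(-0.1, 0.1), fs=FS, band_spec=spec
        )
        res = quantile_iepc(ep, np.ones(n), band=(4, 8))
        assert res.values.max() - res.values.min() < 0.12

    def test_too_few_events_rejected(self, rng):
        ep, mags = self._graded_epochs(rng, n=8)
        with pytest.raises(ValueError):
            quantile_iepc(ep, mags)


class TestERP:
    def _response_with_kernel(self, kernel, times, rng=None, lag_jitter=None):
        n = int(60 * FS)
        x = np.zeros(n)
        for i, t in enumerate(times):
            shift = 0.0 if lag_jitter is None else lag_jitter[i]
            start = int(round((t + shift) * FS)) + int(round(-0.15 * FS))
            seg = kernel.values
            x[start : start + seg.size] += seg
        return ResponseSeries(data=x, fs=FS)

    def test_aligned_erp_recovers_kernel_peak(self, kernel):
        times = np.arange(2.0, 58.0, 1.5)
        resp = self._response_with_kernel(kernel, times)
        t, erp = erp_average(
            resp, LandmarkEvents(times=times, magnitudes=np.ones(times.size))
        )
        k_peak_lag = kernel.lags[np.argmax(kernel.values)]
        assert abs(t[np.argmax(erp)] - k_peak_lag) < 0.02
        assert np.max(erp) == pytest.approx(np.max(kernel.values), rel=0.05)

    def test_misaligned_erp_is_smaller(self, kernel, rng):
        times = np.arange(2.0, 58.0, 1.5)
        lag = rng.uniform(0.04, 0.12, size=times.size)  # variable later landmark
        resp = self._response_with_kernel(kernel, times, lag_jitter=lag)
        events_true = LandmarkEvents(
            times=times + lag, magnitudes=np.ones(times.size)
        )
        events_late = LandmarkEvents(times=times, magnitudes=np.ones(times.size))
        out = compare_alignments(resp, events_true, events_late)
        assert np.max(np.abs(out["erp_a"])) > np.max(np.abs(out["erp_b"]))

    def test_random_alignment_averages_out(self, kernel, rng):
        times = np.arange(2.0, 58.0, 1.5)
        resp = self._response_with_kernel(kernel, times)
        random_times = np.sort(rng.uniform(2.0, 58.0, size=200))
        _, erp = erp_average(
            resp, LandmarkEvents(times=random_times, magnitudes=np.ones(200))
        )
        assert np.max(np.abs(erp)) < 0.25 * np.max(np.abs(kernel.values))

    def test_no_events_raises(self, kernel):
        resp = ResponseSeries(data=np.zeros(int(10 * FS)), fs=FS)
        with pytest.raises(ValueError):
            erp_average(
                resp, LandmarkEvents(times=np.array([0.01]), magnitudes=np.array([1.0]))
            )


class TestNoiseSweep:
    def test_structure_and_low_noise_effects(self, kernel):
        from edgetrack.synth import EventTrainSpec, generate_event_train

        events = generate_event_train(EventTrainSpec(5.7, 2.9, 25.0, seed=9))
        out = noise_robustness_sweep(
            kernel, events, noise_levels=np.array([0.5, 4.0]), n_sims=4, seed=0
        )
        assert out["iepc_dz"].shape == (2,)
        # at mild noise both measures show clear post-event effects
        assert out["iepc_dz"][0] > 1.0
        assert out["power_dz"][0] > 1.0

    def test_effect_arrays_cover_all_levels_and_sims(self, kernel):
        from edgetrack.synth import EventTrainSpec, generate_event_train

        events = generate_event_train(EventTrainSpec(5.7, 2.9, 20.0, seed=10))
        levels = np.array([1.0, 3.0, 6.0])
        out = noise_robustness_sweep(
            kernel, events, noise_levels=levels, n_sims=3, seed=1
        )
        assert out["iepc_effect"].shape == (3, 3)
        assert out["p_bonferroni"].shape == (3,)
        assert np.all(out["p_bonferroni"] <= 1.0)
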