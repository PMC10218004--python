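"""Phase statistics for event-locked envelope tracking.

Implements the discriminating statistics of the analysis:

* IEPC (inter-event phase coherence): the mean resultant length of unit
  phasors across event-locked epochs, per frequency band and time point —
  IEPC(phi, t) = |sum_k exp(i * ph_k(phi, t))| / N.
* CAC (cerebro-acoustic coherence): consistency over time of the phase
  difference between a neural band signal and the same-band speech envelope,
  per utterance (slow utterances split into thirds to equate sample counts).
* A theoretical chance level for IEPC: the expected resultant length of N
  angles drawn from a uniform (zero-concentration von Mises) distribution,
  estimated by Monte Carlo.
* 2D cluster-based permutation tests of IEPC against its pre-event baseline
  (sign-flipping of baseline-subtracted replicate maps, summed-t cluster
  statistic, 4-connectivity over bands x time).
* Spectral and temporal IEPC profiles with peak finding, model-data
  comparison (correlations and a joint two-predictor regression), the
  magnitude-quantile analysis, event-related averaging, and the
  power-vs-IEPC noise robustness sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .containers import (
    BandSpec,
    EpochedPhases,
    Kernel,
    LandmarkEvents,
    NoiseConfig,
    ResponseSeries,
    TFPhaseMap,
)

__all__ = [
    "IEPCMap",
    "CACProfile",
    "ClusterResult",
    "QuantileResult",
    "iepc",
    "theoretical_baseline",
    "cac",
    "cluster_perm_test",
    "ONE_CYCLE_WINDOWS",
    "spectral_profile",
    "find_profile_peaks",
    "temporal_profile",
    "compare_models",
    "quantile_iepc",
    "erp_average",
    "compare_alignments",
    "noise_robustness_sweep",
]

#: One oscillatory cycle at the condition's event rate (s): 1/5.7 and 1/1.9,
#: i.e. the 0-170 ms and 0-500 ms post-event averaging windows.
ONE_CYCLE_WINDOWS = {"regular": (0.0, 0.170), "slow": (0.0, 0.500)}


@dataclass
class IEPCMap:
    """IEPC values (bands x time) with their provenance."""

    values: np.ndarray
    band_spec: BandSpec
    window: tuple[float, float]
    fs: float
    n_events: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("values must be bands x time")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("IEPC values must lie in [0, 1]")

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.values.shape[1]) / self.fs

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        t = self.times
        return (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)


@dataclass
class CACProfile:
    """Per-band cerebro-acoustic coherence, with per-utterance values."""

    values: np.ndarray  # bands, averaged over utterances
    per_utterance: np.ndarray  # bands x utterances
    band_spec: BandSpec

    def __post_init__(self) -> None:
        if np.min(self.values) < -1e-9 or np.max(self.values) > 1 + 1e-9:
            raise ValueError("CAC values must lie in [0, 1]")


@dataclass
class ClusterResult:
    """Suprathreshold clusters of a 2D permutation t test."""

    masks: list[np.ndarray]
    stats: np.ndarray  # summed t per cluster
    p_values: np.ndarray
    n_permutations: int
    t_map: np.ndarray
    t_threshold: float

    def significant(self, alpha: float = 0.01) -> list[np.ndarray]:
        return [m for m, p in zip(self.masks, self.p_values) if p < alpha]


@dataclass
class QuantileResult:
    """Mean theta IEPC per magnitude quantile."""

    values: np.ndarray  # one per quantile
    boundaries: np.ndarray  # magnitude quantile edges, len n_quantiles + 1
    n_per_quantile: np.ndarray = field(default_factory=lambda: np.array([], int))


def iepc(epochs: EpochedPhases) -> IEPCMap:
    """Inter-event phase coherence: resultant length across events."""
    if epochs.n_events < 2:
        raise ValueError("IEPC requires at least 2 events")
    phasors = np.exp(1j * epochs.phase)
    values = np.abs(phasors.mean(axis=0))
    return IEPCMap(
        values=values,
        band_spec=epochs.band_spec,
        window=epochs.window,
        fs=epochs.fs,
        n_events=epochs.n_events,
    )


def theoretical_baseline(
    n_events: int, n_mc: int = 10000, seed: int = 0, return_sd: bool = False
):
    """Expected resultant length of ``n_events`` uniform angles (Monte Carlo).

    The chance level that a finite event count imposes on IEPC: angles from a
    uniform (zero-concentration von Mises) distribution still yield a positive
    resultant, shrinking as 1/sqrt(N).  Returns the Monte-Carlo mean, plus the
    SD across draws if ``return_sd``.
    """
    if n_events < 2:
        raise ValueError("n_events must be >= 2")
    rng = np.random.default_rng(seed)
    chunk = max(1, min(n_mc, int(5e6) // n_events))
    sums = []
    done = 0
    while done < n_mc:
        m = min(chunk, n_mc - done)
        ang = rng.uniform(0.0, 2 * np.pi, size=(m, n_events))
        sums.append(np.abs(np.exp(1j * ang).mean(axis=1)))
        done += m
    r = np.concatenate(sums)
    if return_sd:
        return float(r.mean()), float(r.std(ddof=1))
    return float(r.mean())


def cac(
    neural_tf: TFPhaseMap,
    envelope_tf: TFPhaseMap,
    utterances: list[tuple[float, float]],
    slow_split: int = 1,
) -> CACProfile:
    """Cerebro-acoustic coherence per band, averaged over utterances.

    For each utterance and band, the resultant length of the phase difference
    between the neural signal and the speech envelope across all samples of
    the utterance.  For the slow condition pass ``slow_split=3``: utterances
    are split into three equal parts and the resulting CAC values averaged,
    equating the number of samples with the regular condition.
    """
    if neural_tf.n_samples != envelope_tf.n_samples:
        raise ValueError("neural and envelope phase maps must share a time axis")
    if not np.allclose(neural_tf.band_spec.centers, envelope_tf.band_spec.centers):
        raise ValueError("neural and envelope maps must share a band spec")
    if not utterances:
        raise ValueError("need at least one utterance")
    fs = neural_tf.fs
    lowest = neural_tf.band_spec.centers[0]
    diff = np.exp(1j * (neural_tf.phase - envelope_tf.phase))
    per_utt = np.zeros((neural_tf.band_spec.n_bands, len(utterances)))
    for u, (start, end) in enumerate(utterances):
        i0 = max(0, int(round(start * fs)))
        i1 = min(neural_tf.n_samples, int(round(end * fs)))
        seg_len = (i1 - i0) / slow_split
        if seg_len < fs / lowest:
            import warnings

            warnings.warn(
                f"utterance {u} shorter than one cycle of the lowest band",
                stacklevel=2,
            )
        parts = []
        for p in range(slow_split):
            j0 = i0 + int(round(p * seg_len))
            j1 = i0 + int(round((p + 1) * seg_len))
            if j1 > j0:
                parts.append(np.abs(diff[:, j0:j1].mean(axis=1)))
        per_utt[:, u] = np.mean(parts, axis=0)
    return CACProfile(
        values=per_utt.mean(axis=1),
        per_utterance=per_utt,
        band_spec=neural_tf.band_spec,
    )


def _cluster_stats(
    t_map: np.ndarray, threshold: float
) -> tuple[list[np.ndarray], np.ndarray]:
    """4-connected suprathreshold clusters (both signs) and their summed t."""
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    masks: list[np.ndarray] = []
    stats_: list[float] = []
    for sign in (1.0, -1.0):
        labels, n = ndimage.label(sign * t_map > threshold, structure=structure)
        for lab in range(1, n + 1):
            mask = labels == lab
            masks.append(mask)
            stats_.append(float(t_map[mask].sum()))
    return masks, np.asarray(stats_)


def _t_maps(data_flat: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """One-sample t maps for sign-flipped replicates, vectorised over flips.

    data_flat: replicates x pixels; signs: flips x replicates.  The second
    moment is invariant under sign flips, so only the mean changes.
    """
    n_rep = data_flat.shape[0]
    ss = np.sum(data_flat**2, axis=0)  # pixels
    mean = signs @ data_flat / n_rep  # flips x pixels
    var = (ss[None, :] - n_rep * mean**2) / (n_rep - 1)
    # degenerate pixels (all replicates equal after baseline subtraction)
    # carry only rounding noise; floor the variance at machine-noise scale so
    # their t statistic is ~0 rather than astronomically inflated
    floor = 1e-15 * (ss / n_rep + 1e-15)
    var = np.maximum(var, floor[None, :])
    return mean / np.sqrt(var / n_rep)


def cluster_perm_test(
    maps: np.ndarray,
    times: np.ndarray,
    baseline_window: tuple[float, float] = (-0.4, -0.1),
    n_perm: int = 3000,
    peak_alpha: float = 0.01,
    cluster_alpha: float = 0.01,
    seed: int = 0,
) -> ClusterResult:
    """2D cluster permutation t test of IEPC maps against their baseline.

    ``maps`` are replicate IEPC maps (replicates x bands x time; replicates
    are simulated subjects or independent ensemble members, >= 5).  Each map
    is baseline-corrected by its own mean over ``baseline_window`` per band;
    pixelwise one-sample t values exceeding the ``peak_alpha`` two-sided
    threshold form 4-connected clusters scored by summed t.  The null
    distribution of the maximal |cluster sum| is built by randomly
    sign-flipping replicates ``n_perm`` times.
    """
    maps = np.asarray(maps, float)
    if maps.ndim != 3:
        raise ValueError("maps must be replicates x bands x time")
    n_rep, n_bands, n_time = maps.shape
    if n_rep < 5:
        raise ValueError("cluster test needs at least 5 replicates")
    times = np.asarray(times, float)
    bmask = (times >= baseline_window[0] - 1e-9) & (times <= baseline_window[1] + 1e-9)
    if not bmask.any():
        raise ValueError("baseline window outside the epoch")
    data = maps - maps[:, :, bmask].mean(axis=2, keepdims=True)
    data_flat = data.reshape(n_rep, -1)

    t_crit = float(sps.t.ppf(1 - peak_alpha / 2, df=n_rep - 1))
    t_obs = _t_maps(data_flat, np.ones((1, n_rep)))[0].reshape(n_bands, n_time)
    masks, stats_ = _cluster_stats(t_obs, t_crit)

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    chunk = max(1, int(2e7) // max(1, data_flat.shape[1]))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        signs = rng.choice([-1.0, 1.0], size=(m, n_rep))
        t_perm = _t_maps(data_flat, signs)
        for i in range(m):
            _, s = _cluster_stats(t_perm[i].reshape(n_bands, n_time), t_crit)
            null_max[done + i] = np.abs(s).max() if s.size else 0.0
        done += m

    if stats_.size:
        p = (1 + (null_max[None, :] >= np.abs(stats_)[:, None]).sum(axis=1)) / (
            n_perm + 1
        )
    else:
        p = np.asarray([])
    order = np.argsort(p) if p.size else np.array([], int)
    return ClusterResult(
        masks=[masks[i] for i in order],
        stats=stats_[order] if stats_.size else stats_,
        p_values=p[order] if p.size else p,
        n_permutations=n_perm,
        t_map=t_obs,
        t_threshold=t_crit,
    )


def spectral_profile(
    iepc_map: IEPCMap,
    condition: str = "slow",
    window: tuple[float, float] | None = None,
    baseline_window: tuple[float, float] = (-0.4, -0.1),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-band mean IEPC over the condition's one-cycle post-event window.

    Returns ``(profile, baseline)``: the profile is the IEPC averaged over
    0-170 ms (regular) or 0-500 ms (slow) after the event; the baseline is
    the per-band pre-event average (default -400..-100 ms).
    """
    if window is None:
        try:
            window = ONE_CYCLE_WINDOWS[condition]
        except KeyError:
            raise ValueError(f"unknown condition {condition!r}") from None
    wmask = iepc_map.time_mask(window)
    bmask = iepc_map.time_mask(baseline_window)
    if not wmask.any():
        raise ValueError("profile window outside the epoch")
    profile = iepc_map.values[:, wmask].mean(axis=1)
    baseline = (
        iepc_map.values[:, bmask].mean(axis=1)
        if bmask.any()
        else np.zeros(profile.size)
    )
    return profile, baseline


def find_profile_peaks(
    profile: np.ndarray,
    baseline: np.ndarray | None = None,
    ensemble_sd: np.ndarray | float = 0.0,
    smooth: int = 3,
    min_prominence: float = 0.02,
) -> np.ndarray:
    """Indices of prominent local maxima of a spectral IEPC profile.

    The profile is smoothed with a ``smooth``-band moving average (reflected
    edges); peaks are interior local maxima whose prominence exceeds twice
    the ensemble SD (the realisation-to-realisation noise scale of the
    profile) or ``min_prominence``, whichever is larger.  The pre-event
    baseline is not used as a gate: in rhythmic input, phase coherence at the
    event rate is genuinely elevated both before and after events, and a
    spectral peak is a statement about profile shape, not about exceeding
    baseline.  An extremum at the grid edge is never counted.
    """
    from scipy.signal import find_peaks

    profile = np.asarray(profile, float)
    if smooth > 1:
        pad = smooth // 2
        padded = np.pad(profile, pad, mode="reflect")
        kernel = np.ones(smooth) / smooth
        smoothed = np.convolve(padded, kernel, mode="valid")[: profile.size]
    else:
        smoothed = profile
    gate = max(float(np.max(2.0 * np.asarray(ensemble_sd, float))), min_prominence)
    idx, _ = find_peaks(smoothed, prominence=gate)
    return idx


def temporal_profile(
    iepc_map: IEPCMap,
    center: float = 1.9,
    half_octaves: float = 0.25,
    n_mc: int = 2000,
    seed: int = 0,
) -> dict:
    """Band-averaged IEPC time course around the event rate, with chance level.

    Averages IEPC over bands within ``center * 2**(+-half_octaves)`` (half an
    octave around 1.9 Hz by default) and attaches the uniform-null Monte-Carlo
    baseline for the map's event count.  Returns a dict with ``times``,
    ``values``, ``baseline``, ``baseline_sd`` and ``exceeds`` (boolean time
    points above baseline + 2 SD).
    """
    centers = iepc_map.band_spec.centers
    sel = (centers >= center * 2.0**-half_octaves) & (
        centers <= center * 2.0**half_octaves
    )
    if not sel.any():
        raise ValueError("no bands within the requested range")
    values = iepc_map.values[sel].mean(axis=0)
    base, base_sd = theoretical_baseline(
        iepc_map.n_events, n_mc=n_mc, seed=seed, return_sd=True
    )
    return {
        "times": iepc_map.times,
        "values": values,
        "baseline": base,
        "baseline_sd": base_sd,
        "exceeds": values > base + 2 * base_sd,
    }


def compare_models(
    observed: np.ndarray,
    predicted: dict[str, np.ndarray],
) -> dict:
    """Correlate observed profiles with model predictions; joint regression.

    ``observed`` is replicates x points (simulated subjects standing in for
    participants); ``predicted`` maps model names (e.g. ``osc``, ``er``) to
    profiles on the same grid.  Per replicate: Pearson correlation with each
    model and a joint OLS of the observed profile on both predictors (with
    intercept).  Second level: one-sample t tests of the betas across
    replicates.  Constant (degenerate) profiles yield NaN correlations.
    """
    observed = np.atleast_2d(np.asarray(observed, float))
    names = list(predicted)
    P = np.column_stack([np.asarray(predicted[k], float) for k in names])
    if P.shape[0] != observed.shape[1]:
        raise ValueError("observed and predicted profiles must share a grid")
    X = np.column_stack([np.ones(P.shape[0]), P])
    n_rep = observed.shape[0]
    corrs = {k: np.full(n_rep, np.nan) for k in names}
    betas = np.zeros((n_rep, len(names)))
    for r in range(n_rep):
        y = observed[r]
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        betas[r] = coef[1:]
        for j, k in enumerate(names):
            if np.std(y) > 0 and np.std(P[:, j]) > 0:
                corrs[k][r] = np.corrcoef(y, P[:, j])[0, 1]
    result = {
        "models": names,
        "correlations": corrs,
        "betas": {k: betas[:, j] for j, k in enumerate(names)},
    }
    if n_rep > 1:
        tt = {k: sps.ttest_1samp(betas[:, j], 0.0) for j, k in enumerate(names)}
        result["beta_t"] = {k: float(v.statistic) for k, v in tt.items()}
        result["beta_p"] = {k: float(v.pvalue) for k, v in tt.items()}
    return result


def quantile_iepc(
    epochs: EpochedPhases,
    magnitudes: np.ndarray,
    n_quantiles: int = 5,
    band: tuple[float, float] = (4.0, 8.0),
    rate_hz: float | None = None,
) -> QuantileResult:
    """Theta IEPC per event-magnitude quantile.

    Events are split into ``n_quantiles`` equal-count groups by magnitude
    (stable ties by event order).  Within each group, IEPC is averaged over
    bands with centers in ``band`` and, per band, over one cycle
    (0..1/center s) after the event; ``rate_hz`` overrides the cycle length
    with a fixed 1/rate window.
    """
    magnitudes = np.asarray(magnitudes, float)
    if magnitudes.size != epochs.n_events:
        raise ValueError("one magnitude per epoch required")
    if epochs.n_events < n_quantiles * 2:
        raise ValueError("too few events for the requested quantile count")
    centers = epochs.band_spec.centers
    bsel = np.flatnonzero((centers >= band[0]) & (centers <= band[1]))
    if bsel.size == 0:
        raise ValueError("no bands within the requested range")
    order = np.argsort(magnitudes, kind="stable")
    groups = np.array_split(order, n_quantiles)
    t = epochs.times
    values = np.zeros(n_quantiles)
    counts = np.zeros(n_quantiles, int)
    for q, grp in enumerate(groups):
        ph = epochs.phase[grp]
        map_q = np.abs(np.exp(1j * ph).mean(axis=0))  # bands x time
        per_band = []
        for b in bsel:
            cycle = 1.0 / (rate_hz if rate_hz is not None else centers[b])
            tmask = (t >= -1e-9) & (t <= cycle + 1e-9)
            per_band.append(map_q[b, tmask].mean())
        values[q] = float(np.mean(per_band))
        counts[q] = grp.size
    sorted_m = magnitudes[order]
    edges = [sorted_m[0]]
    acc = 0
    for grp in groups:
        acc += grp.size
        edges.append(sorted_m[min(acc, sorted_m.size) - 1])
    return QuantileResult(
        values=values, boundaries=np.asarray(edges), n_per_quantile=counts
    )


def _epoch_series(
    x: np.ndarray,
    fs: float,
    events: LandmarkEvents,
    window: tuple[float, float],
) -> np.ndarray:
    n_pre = int(round(window[0] * fs))
    n_post = int(round(window[1] * fs))
    centers = np.round(events.times * fs).astype(int)
    ok = (centers + n_pre >= 0) & (centers + n_post < x.size)
    centers = centers[ok]
    if centers.size == 0:
        raise ValueError("no events usable with the requested window")
    offsets = np.arange(n_pre, n_post + 1)
    return x[centers[:, None] + offsets[None, :]]


def erp_average(
    resp: ResponseSeries,
    events: LandmarkEvents,
    window: tuple[float, float] = (-0.1, 0.3),
    baseline: tuple[float, float] = (-0.1, 0.0),
    channel: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-corrected event-related average of a broadband signal.

    Returns ``(times, erp)``.  The input should already be band-passed to the
    broadband range of interest (e.g. 1-40 Hz).
    """
    x = resp.channel(channel)
    ep = _epoch_series(x, resp.fs, events, window)
    t = window[0] + np.arange(ep.shape[1]) / resp.fs
    bmask = (t >= baseline[0] - 1e-9) & (t <= baseline[1] + 1e-9)
    ep = ep - ep[:, bmask].mean(axis=1, keepdims=True)
    return t, ep.mean(axis=0)


def compare_alignments(
    resp: ResponseSeries,
    events_a: LandmarkEvents,
    events_b: LandmarkEvents,
    window: tuple[float, float] = (-0.1, 0.3),
    baseline: tuple[float, float] = (-0.1, 0.0),
    channel: int = 0,
) -> dict:
    """ERPs under two event alignments plus a pointwise Welch t comparison."""
    x = resp.channel(channel)
    out = {}
    eps = {}
    for name, ev in (("a", events_a), ("b", events_b)):
        ep = _epoch_series(x, resp.fs, ev, window)
        t = window[0] + np.arange(ep.shape[1]) / resp.fs
        bmask = (t >= baseline[0] - 1e-9) & (t <= baseline[1] + 1e-9)
        ep = ep - ep[:, bmask].mean(axis=1, keepdims=True)
        eps[name] = ep
        out[f"erp_{name}"] = ep.mean(axis=0)
    out["times"] = t
    tt = sps.ttest_ind(eps["a"], eps["b"], axis=0, equal_var=False)
    out["t"] = tt.statistic
    out["p"] = tt.pvalue
    return out


def noise_robustness_sweep(
    kernel: Kernel,
    events: LandmarkEvents,
    fs: float = 400.0,
    noise_levels: np.ndarray | None = None,
    n_sims: int = 20,
    band: tuple[float, float] = (4.0, 8.0),
    epoch_window: tuple[float, float] = (-0.5, 0.5),
    baseline_window: tuple[float, float] = (-0.4, -0.1),
    jitter_sd: float = 0.010,
    seed: int = 0,
) -> dict:
    """Effect of noise level on post-event theta power vs. theta IEPC.

    For each noise level L in 1..10 (noise RMS = L x response RMS, i.e.
    SNR = 1/L) and each of ``n_sims`` simulated responses, the post-event
    change (one cycle per band after the event vs. the pre-event baseline) is
    computed for band amplitude-squared (power) and for IEPC, standardised by
    the baseline's variability across events.  Per level, effect sizes
    (Cohen's dz across simulations) for both measures are reported together
    with a two-sided paired t test between them, Bonferroni-corrected across
    levels.
    """
    from .evoked import add_pink_noise, convolve_kernel
    from .oscillator import build_event_input
    from .tf import epoch_amplitudes, epoch_phases, make_band_spec, tf_decompose

    if noise_levels is None:
        noise_levels = np.arange(1, 11)
    noise_levels = np.asarray(noise_levels, float)
    if noise_levels.size == 0 or n_sims < 2:
        raise ValueError("need at least one level and two simulations")
    spec = make_band_spec(fmin=band[0], fmax=band[1], half_width=0.5)
    duration = float(events.times[-1]) + kernel.lag_window[1] + 0.5
    rng = np.random.default_rng(seed)

    iepc_eff = np.zeros((noise_levels.size, n_sims))
    power_eff = np.zeros((noise_levels.size, n_sims))
    for li, level in enumerate(noise_levels):
        for si in range(n_sims):
            jseed = int(rng.integers(2**31 - 1))
            driven = build_event_input(
                events, fs=fs, duration=duration, jitter_sd=jitter_sd, seed=jseed
            )
            clean = convolve_kernel(driven, kernel)
            # noise levels are amplitude multiples of the response magnitude
            cfg = NoiseConfig(
                snr=1.0 / level, jitter_sd=jitter_sd, snr_domain="amplitude"
            )
            noisy = add_pink_noise(clean, cfg, rng=rng)
            tfm = tf_decompose(noisy, spec)
            ph = epoch_phases(tfm, events, window=epoch_window)
            amp = epoch_amplitudes(tfm, events, window=epoch_window)
            t = ph.times
            bmask = (t >= baseline_window[0] - 1e-9) & (t <= baseline_window[1] + 1e-9)
            iepc_map = np.abs(np.exp(1j * ph.phase).mean(axis=0))
            power = (amp**2).mean(axis=0)  # bands x time
            i_post, p_post, i_base, p_base = [], [], [], []
            for b, c in enumerate(spec.centers):
                pmask = (t >= -1e-9) & (t <= 1.0 / c + 1e-9)
                i_post.append(iepc_map[b, pmask].mean())
                p_post.append(power[b, pmask].mean())
                i_base.append(iepc_map[b, bmask])
                p_base.append(power[b, bmask])
            i_base = np.concatenate(i_base)
            p_base = np.concatenate(p_base)
            iepc_eff[li, si] = (np.mean(i_post) - i_base.mean()) / (
                i_base.std(ddof=1) + 1e-12
            )
            power_eff[li, si] = (np.mean(p_post) - p_base.mean()) / (
                p_base.std(ddof=1) + 1e-12
            )

    def dz(x: np.ndarray) -> np.ndarray:
        return x.mean(axis=1) / (x.std(axis=1, ddof=1) + 1e-12)

    tt = sps.ttest_rel(iepc_eff, power_eff, axis=1)
    p_bonf = np.minimum(tt.pvalue * noise_levels.size, 1.0)
    return {
        "noise_levels": noise_levels,
        "iepc_effect": iepc_eff,
        "power_effect": power_eff,
        "iepc_dz": dz(iepc_eff),
        "power_dz": dz(power_eff),
        "t": tt.statistic,
        "p_bonferroni": p_bonf,
    }
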