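"""Synthetic stimulus and response generation.

Real speech stimuli and MEG recordings are replaced by parametric surrogates
that reproduce the statistics the pipeline depends on:

* event trains with the landmark statistics of natural and 3x-slowed speech
  (instantaneous event frequency 5.7 Hz, SD 2.9 Hz at the regular rate;
  1.9 Hz, SD 1.0 Hz slowed), organised into utterances separated by
  500-1100 ms silences;
* speech-like amplitude-modulated waveforms where every event produces exactly
  one acoustic edge (peakRate) and one envelope peak (peakEnv);
* a synthetic biphasic evoked-response kernel (~350 ms main deflection,
  dominant theta-range spectral content) standing in for a data-estimated
  temporal response function;
* MEG-like responses: jittered, magnitude-scaled event train convolved with
  the kernel plus 1/f noise.

Event timing mimics the structure of syllabic rhythm in read speech, which
is locally quasi-periodic: within a prosodic phrase, landmark events sit on
a jittered beat grid (period = 1/local tempo, Gaussian jitter of ~12% of the
period), with occasional extra events between beats (fast syllable runs) and
occasional skipped beats (hesitations); the local tempo varies from phrase
to phrase around the speaker's base rate (symmetric truncated-normal
spread).  This is the only structure compatible with the joint statistics of
natural read speech — a wide local-rate histogram together with a strong
spectral comb at the mean event rate and a near-unity ratio of counting rate
to mean rate; independent heavy-tailed intervals with the same marginal
moments cannot reproduce the comb, and without the comb the low-frequency
phase-coherence component of the evoked-response model disappears.

``mean_rate`` and ``rate_sd`` are the moments of the *local* instantaneous
event frequency, estimated (as one would build the rate histogram of a real
stimulus) from event counts in windows of 1.5 mean periods tiled over
utterances; ``instantaneous_rate_stats`` implements exactly this estimator.  Because the mapping from timing parameters to these moments
has no closed form, each generated train self-calibrates: the tempo scale
and spread are adjusted in a short fixed-point iteration until the realised
moments match the spec, so every stimulus — like the single fixed stimulus
set of a listening experiment — has the stated rate statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import (
    EventInputSeries,
    Kernel,
    LandmarkEvents,
    NoiseConfig,
    ResponseSeries,
    Waveform,
)
from .evoked import add_pink_noise, convolve_kernel

__all__ = [
    "EventTrainSpec",
    "SyntheticKernelSpec",
    "REGULAR_SPEC",
    "SLOW_SPEC",
    "generate_event_train",
    "generate_event_train_with_utterances",
    "stretch_event_train",
    "instantaneous_rate_stats",
    "generate_am_waveform",
    "generate_synthetic_kernel",
    "SyntheticResponse",
    "generate_synthetic_response",
]


@dataclass
class EventTrainSpec:
    """Statistics of a landmark (peakRate) event train.

    mean_rate / rate_sd are the moments of the instantaneous event frequency
    (Hz); utterances of 10-60 s are separated by silences drawn uniformly from
    ``silence_range`` (s).
    """

    mean_rate: float
    rate_sd: float
    duration: float
    silence_range: tuple[float, float] = (0.5, 1.1)
    utterance_range: tuple[float, float] = (10.0, 60.0)
    phrase_events: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rate <= 0:
            raise ValueError("mean_rate must be positive")
        if self.rate_sd < 0:
            raise ValueError("rate_sd must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.silence_range[0] > self.silence_range[1]:
            raise ValueError("silence_range min must not exceed max")
        if self.utterance_range[0] > self.utterance_range[1]:
            raise ValueError("utterance_range min must not exceed max")
        if self.phrase_events <= 0:
            raise ValueError("phrase_events must be positive")


#: Regular-speech condition: landmark frequency 5.7 Hz (SD 2.9).
REGULAR_SPEC = EventTrainSpec(mean_rate=5.7, rate_sd=2.9, duration=390.0)
#: Slowed (one-third rate) condition: landmark frequency 1.9 Hz (SD 1.0).
SLOW_SPEC = EventTrainSpec(mean_rate=1.9, rate_sd=1.0, duration=1170.0)


#: Beat-grid timing constants (fractions of the local beat period / per-beat
#: probabilities): Gaussian jitter of beat placement, probability of an extra
#: event between beats (fast syllable run), probability of a skipped beat
#: (hesitation, balanced against insertions so the counting rate equals the
#: beat rate), and the minimum separation below which events merge.
BEAT_JITTER = 0.12
P_EXTRA = 0.20
P_SKIP = 0.20
MIN_SEP = 0.12

#: Local-rate estimator window, in mean event periods: the rate histogram is
#: built from event counts in windows of this duration tiled over utterances.
RATE_WINDOW_PERIODS = 1.5


def _tempo_pool(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    """n phrase tempi from a symmetric truncated-normal spread, stratified.

    One uniform per equal-probability stratum is mapped through the quantile
    function (truncation at mean +- 2 SD, floored at 15% of the mean), then
    shuffled: the marginal and phrase-to-phrase independence are intact, but
    the empirical moments of a single stimulus converge much faster than
    1/sqrt(n).
    """
    if sd <= 0:
        return np.full(n, mean)
    from scipy.stats import truncnorm

    lo = max(mean - 2.0 * sd, 0.15 * mean)
    hi = mean + 2.0 * sd
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = (np.arange(n) + rng.uniform(0.0, 1.0, size=n)) / n
    tempi = truncnorm.ppf(u, a, b, loc=mean, scale=sd)
    rng.shuffle(tempi)
    return tempi


def _phrase_times(
    rng: np.random.Generator,
    start: float,
    end: float,
    period: float,
    mech_scale: float = 1.0,
) -> np.ndarray:
    """Event times of one phrase: jittered beats + extras - skips, merged.

    ``mech_scale`` < 1 proportionally weakens the within-phrase variability
    mechanisms (used when a spec requests a rate SD below their default
    contribution).
    """
    sigma = BEAT_JITTER * mech_scale
    p_extra = P_EXTRA * mech_scale**2
    p_skip = P_SKIP * mech_scale**2
    n_beats = int(np.ceil((end - start) / period)) + 1
    grid = start + (np.arange(n_beats) + 0.5) * period
    beats = grid + sigma * period * rng.standard_normal(n_beats)
    beats = beats[rng.random(n_beats) > p_skip]
    extra_mask = rng.random(n_beats - 1) < p_extra
    offsets = rng.uniform(0.25, 0.75, size=n_beats - 1)
    extras = (grid[:-1] + offsets * period)[extra_mask]
    t = np.concatenate([beats, extras])
    is_beat = np.concatenate(
        [np.ones(beats.size, dtype=bool), np.zeros(extras.size, dtype=bool)]
    )
    order = np.argsort(t)
    t, is_beat = t[order], is_beat[order]
    inside = (t >= start) & (t < end)
    t, is_beat = t[inside], is_beat[inside]
    if t.size > 1:
        iv = np.diff(t)
        keep = np.concatenate([[True], iv > MIN_SEP * period])
        t, is_beat = t[keep], is_beat[keep]
    return t, is_beat


def _generate_raw(
    spec: EventTrainSpec,
    tempo_mean: float,
    tempo_sd: float,
    rng: np.random.Generator,
    mech_scale: float = 1.0,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    phrase_len = spec.phrase_events / max(tempo_mean, 1e-9)
    n_pool = (
        int(np.ceil(spec.duration / phrase_len))
        + int(np.ceil(spec.duration / spec.utterance_range[0]))
        + 8
    )
    pool = iter(_tempo_pool(rng, tempo_mean, tempo_sd, n_pool))
    times: list[np.ndarray] = []
    beat_flags: list[np.ndarray] = []
    utterances: list[tuple[float, float]] = []
    t = 0.0
    while t < spec.duration:
        utt_end = min(t + rng.uniform(*spec.utterance_range), spec.duration)
        utt_start = t
        cursor = t
        got_any = False
        while cursor < utt_end - 1e-9:
            tempo = next(pool)
            ph_end = min(cursor + phrase_len, utt_end)
            ev, is_beat = _phrase_times(rng, cursor, ph_end, 1.0 / tempo, mech_scale)
            if ev.size:
                times.append(ev)
                beat_flags.append(is_beat)
                got_any = True
            cursor = ph_end
        if got_any:
            utterances.append((utt_start, utt_end))
        t = utt_end + rng.uniform(*spec.silence_range)
    if not times:
        return np.asarray([]), np.asarray([], dtype=bool), utterances
    all_t = np.concatenate(times)
    all_b = np.concatenate(beat_flags)
    order = np.argsort(all_t)
    all_t, all_b = all_t[order], all_b[order]
    if all_t.size > 1:
        iv = np.diff(all_t)
        keep = np.concatenate([[True], iv > MIN_SEP / max(tempo_mean, 1e-9)])
        all_t, all_b = all_t[keep], all_b[keep]
    return all_t, all_b, utterances


def _local_rates(
    times: np.ndarray,
    utterances: list[tuple[float, float]],
    window_periods: float = RATE_WINDOW_PERIODS,
) -> np.ndarray:
    """Local rates: event counts in fixed windows tiled over utterances.

    The window duration is ``window_periods`` mean event periods, with the
    mean period taken from the train's own within-utterance counting rate, so
    the estimator is scale-free (a stretched train yields the same histogram
    shape at one third the rate).
    """
    n_events = 0
    total_time = 0.0
    for start, end in utterances:
        n_events += int(np.sum((times >= start) & (times <= end)))
        total_time += end - start
    if n_events < 2 or total_time <= 0:
        return np.asarray([])
    window = window_periods * total_time / n_events
    out = []
    for start, end in utterances:
        edges = np.arange(start, end + 1e-9, window)
        if edges.size < 2:
            continue
        counts, _ = np.histogram(times, edges)
        out.append(counts / window)
    if not out:
        return np.asarray([])
    return np.concatenate(out)


def _draw_magnitudes(
    rng: np.random.Generator, is_beat: np.ndarray
) -> np.ndarray:
    """Log-normal magnitudes clipped to (0, 1].

    Beat events (stressed syllable onsets) carry larger acoustic edges than
    inserted off-beat events (reduced syllables), as in natural speech.
    """
    n = is_beat.size
    m = np.where(
        is_beat,
        rng.lognormal(mean=-1.0, sigma=0.55, size=n),
        rng.lognormal(mean=-1.9, sigma=0.50, size=n),
    )
    return np.clip(m, 1e-6, 1.0)


def generate_event_train_with_utterances(
    spec: EventTrainSpec,
) -> tuple[LandmarkEvents, list[tuple[float, float]]]:
    """Generate a peakRate event train plus its utterance segmentation.

    The tempo scale and spread self-calibrate in a short fixed-point
    iteration so that the realised local-rate moments (see
    ``instantaneous_rate_stats``) match ``spec.mean_rate`` / ``spec.rate_sd``.
    Returns the events and a list of (start, end) utterance intervals in
    seconds.  Deterministic given ``spec.seed``.
    """
    # within-phrase mechanisms contribute ~0.54 CV to the local-rate
    # histogram at full strength; the remainder is tempo spread.  Specs
    # requesting less than the mechanism floor weaken the mechanisms instead.
    MECH_CV = 0.54
    TEMPO_CV_MIN = 0.07  # speakers always drift in tempo at least this much
    cv_tot = spec.rate_sd / spec.mean_rate if spec.mean_rate > 0 else 0.0
    cv_mech_target = np.sqrt(max(cv_tot**2 - TEMPO_CV_MIN**2, 0.0))
    mech_scale = min(1.0, cv_mech_target / MECH_CV) if cv_tot > 0 else 0.0
    tempo_mean = spec.mean_rate
    tempo_floor = TEMPO_CV_MIN * spec.mean_rate if cv_tot > TEMPO_CV_MIN else 0.0
    tempo_sd = max(
        spec.mean_rate
        * np.sqrt(max(cv_tot**2 - (MECH_CV * mech_scale) ** 2, 0.0)),
        tempo_floor,
    )
    times = np.asarray([])
    is_beat = np.asarray([], dtype=bool)
    utterances: list[tuple[float, float]] = []
    for _ in range(4):
        rng = np.random.default_rng(spec.seed)  # same stream every iteration
        times, is_beat, utterances = _generate_raw(
            spec, tempo_mean, tempo_sd, rng, mech_scale
        )
        rates = _local_rates(times, utterances)
        if rates.size < 8:
            break  # too short to calibrate; accept the raw draw
        m, s = float(rates.mean()), float(rates.std(ddof=1))
        if abs(m - spec.mean_rate) < 0.005 * spec.mean_rate and (
            spec.rate_sd == 0 or abs(s - spec.rate_sd) < 0.01 * spec.rate_sd
        ):
            break
        tempo_mean *= spec.mean_rate / m
        if spec.rate_sd > 0 and s > 0 and tempo_sd > 0:
            tempo_sd = max(tempo_sd * spec.rate_sd / s, tempo_floor)
    final_rng = np.random.default_rng(spec.seed)
    final_rng.bit_generator.advance(10**6)  # decouple magnitudes from timing
    mags = _draw_magnitudes(final_rng, is_beat)
    return (
        LandmarkEvents(times=times, magnitudes=mags, kind="peakRate"),
        utterances,
    )


def generate_event_train(spec: EventTrainSpec) -> LandmarkEvents:
    """Generate a peakRate event train with the spec's frequency statistics."""
    events, _ = generate_event_train_with_utterances(spec)
    return events


def stretch_event_train(events: LandmarkEvents, factor: float = 3.0) -> LandmarkEvents:
    """Slow a train by ``factor``: times x factor, magnitudes x 1/factor.

    Mirrors the effect of time-stretching the underlying envelope: edges occur
    ``factor`` times later and rise ``factor`` times slower.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    return LandmarkEvents(
        times=events.times * factor,
        magnitudes=events.magnitudes / factor,
        kind=events.kind,
    )


def instantaneous_rate_stats(
    events: LandmarkEvents,
    utterances: list[tuple[float, float]] | None = None,
    window_periods: float = RATE_WINDOW_PERIODS,
) -> tuple[float, float]:
    """Empirical mean and SD of the local instantaneous event frequency (Hz).

    The rate histogram is built from event counts in windows of
    ``window_periods`` mean event periods tiled over utterances — the
    resolution at which the rate histogram of a speech stimulus is read;
    silences are excluded when ``utterances`` is given.
    """
    if len(events) < 6:
        raise ValueError("too few events for rate statistics")
    if utterances is None:
        utterances = [(float(events.times[0]), float(events.times[-1]))]
    rates = _local_rates(events.times, utterances, window_periods=window_periods)
    if rates.size < 2:
        raise ValueError("too few within-utterance windows for rate statistics")
    return float(rates.mean()), float(rates.std(ddof=1))


def _bump(t: np.ndarray, onset: float, rise: float, decay: float) -> np.ndarray:
    """Asymmetric raised-cosine bump: rise over ``rise`` s, decay over ``decay`` s."""
    out = np.zeros_like(t)
    up = (t >= onset) & (t < onset + rise)
    out[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - onset) / rise))
    down = (t >= onset + rise) & (t < onset + rise + decay)
    out[down] = 0.5 * (1 + np.cos(np.pi * (t[down] - onset - rise) / decay))
    return out


def generate_am_waveform(
    events: LandmarkEvents,
    fs: float = 16000.0,
    carrier_hz: float = 220.0,
    rise: float = 0.06,
    decay: float = 0.12,
    duration: float | None = None,
) -> Waveform:
    """Carrier tone amplitude-modulated by one asymmetric bump per event.

    The bump rises over ``rise`` s and decays over ``decay`` s; its steepest
    rise (the peakRate landmark) is placed at the event time, so downstream
    envelope extraction recovers one peakRate (at the event, +-20 ms) and one
    later peakEnv per well-separated event, with peakRate magnitude
    proportional to event magnitude / rise time.
    """
    if fs < 1000:
        raise ValueError("fs must be >= 1000 Hz for an audio-like carrier")
    if duration is None:
        duration = (float(events.times[-1]) + rise + decay + 0.2) if len(events) else 1.0
    if len(events) and np.any(np.diff(events.times) < rise):
        warnings.warn(
            "events closer than the bump rise time; landmarks may merge",
            stacklevel=2,
        )
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    env = np.zeros(n)
    for time, mag in zip(events.times, events.magnitudes):
        onset = time - rise / 2.0  # steepest rise at the event time
        i0 = max(0, int(np.floor(onset * fs)))
        i1 = min(n, int(np.ceil((onset + rise + decay) * fs)) + 1)
        if i1 > i0:
            env[i0:i1] += mag * _bump(t[i0:i1], onset, rise, decay)
    carrier = np.sin(2 * np.pi * carrier_hz * t)
    return Waveform(samples=env * carrier, fs=fs)


@dataclass
class SyntheticKernelSpec:
    """Shape of the synthetic biphasic evoked-response kernel.

    The kernel is a positive deflection at ``pos_latency`` followed by a
    negative one at ``neg_latency`` (Gaussian components, s / a.u.), tapered to
    exactly zero outside [0, duration].  Default geometry gives a ~350 ms main
    deflection with dominant spectral content in the theta band.
    """

    fs: float = 400.0
    duration: float = 0.35
    lag_window: tuple[float, float] = (-0.15, 0.45)
    pos_latency: float = 0.09
    pos_width: float = 0.025
    pos_amplitude: float = 1.0
    neg_latency: float = 0.16
    neg_width: float = 0.03
    neg_amplitude: float = -0.8
    amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        start, end = self.lag_window
        if not (start <= 0.0 and end >= self.duration):
            raise ValueError("lag_window must span the kernel support [0, duration]")


def generate_synthetic_kernel(spec: SyntheticKernelSpec) -> Kernel:
    """Construct the biphasic kernel on the lag grid of ``spec.lag_window``."""
    start, end = spec.lag_window
    n = int(round((end - start) * spec.fs)) + 1
    lags = start + np.arange(n) / spec.fs
    shape = spec.pos_amplitude * np.exp(
        -0.5 * ((lags - spec.pos_latency) / spec.pos_width) ** 2
    ) + spec.neg_amplitude * np.exp(
        -0.5 * ((lags - spec.neg_latency) / spec.neg_width) ** 2
    )
    taper = np.zeros_like(lags)
    inside = (lags >= 0) & (lags <= spec.duration)
    taper[inside] = np.sin(np.pi * lags[inside] / spec.duration) ** 2
    values = spec.amplitude * shape * taper
    return Kernel(values=values, fs=spec.fs, lag_window=spec.lag_window)


@dataclass
class SyntheticResponse:
    """A simulated response plus the ground truth that generated it."""

    response: ResponseSeries
    stimulus: EventInputSeries  # unjittered, magnitude-scaled impulses
    events: LandmarkEvents  # original (nonjittered) event table
    realized_times: np.ndarray  # jittered event times actually used


def generate_synthetic_response(
    events: LandmarkEvents,
    kernel: Kernel,
    noise: NoiseConfig | None,
    fs: float,
    seed: int = 0,
    duration: float | None = None,
) -> SyntheticResponse:
    """Simulate an MEG-like response to an event train.

    The response is the jittered, magnitude-scaled impulse train convolved
    with ``kernel``, plus 1/f noise at the configured SNR.  Phase analyses use
    the retained original (nonjittered) event times.
    """
    if abs(kernel.fs - fs) > 1e-9:
        raise ValueError(f"kernel fs={kernel.fs} does not match requested fs={fs}")
    rng = np.random.default_rng(seed)
    if duration is None:
        duration = (float(events.times[-1]) if len(events) else 0.0) + kernel.lag_window[1] + 0.5
    n = int(round(duration * fs))

    jitter_sd = noise.jitter_sd if noise is not None else 0.0
    jittered = events.times + (rng.normal(0.0, jitter_sd, size=len(events)) if jitter_sd > 0 else 0.0)

    def impulse_train(times: np.ndarray) -> np.ndarray:
        s = np.zeros(n)
        idx = np.round(times * fs).astype(int)
        ok = (idx >= 0) & (idx < n)
        np.add.at(s, idx[ok], events.magnitudes[ok])
        return s

    stim = EventInputSeries(s=impulse_train(events.times), fs=fs)
    driven = EventInputSeries(s=impulse_train(jittered), fs=fs)
    resp = convolve_kernel(driven, kernel)
    if noise is not None:
        resp = add_pink_noise(resp, noise, rng=rng)
    return SyntheticResponse(
        response=resp, stimulus=stim, events=events, realized_times=jittered
    )
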