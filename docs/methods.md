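# Methods

`edgetrack` asks a mechanistic question about speech envelope tracking: when
low-frequency (1–10 Hz) neural phase locks to the amplitude envelope of
speech, is that the entrainment of an endogenous oscillator, or the
superposition of transient evoked responses to acoustic edges?  The package
implements both candidate mechanisms as generative models, drives them with
synthetic speech-like stimuli, and quantifies their diverging predictions
with event-locked phase statistics.

## The two response models

Both models receive the same input `s(t)`: a sparse impulse series with a
scaled peakRate magnitude at each acoustic-edge time and zeros elsewhere.
Magnitudes are min–max scaled to [0.5, 1] *within* each speech-rate
condition, expressing rate-normalised edge encoding; Gaussian temporal
jitter (SD 10 ms regular / 30 ms slowed speech) models the variable latency
of responses to non-transient events, and all phase analyses use the
original, unjittered event times.

**Oscillatory entrainment.**  A coupled-oscillator system with a
non-decaying amplitude attractor,

    dθ/dt = 2πF − c·s(t)·r·sin θ
    dr/dt = r(1 − r²) + c·s(t)·cos θ,

free-runs at its natural frequency `F` (5.7 Hz regular / 1.9 Hz slow — the
condition's event rate) on the limit cycle `r = 1` and is pulled toward
phase θ = 0 by each input impulse.  The predicted response is
`cos θ · r`.  Integration is forward Euler at the 400 Hz analysis rate: the
system is slow relative to the step, the free-run phase increment is then
*exact* (2πF/fs per step, testable to machine precision), and the coupling
calibration is closed-form.  Interpreting "maximal phase shift" as π (the
largest meaningful correction distance), a single-sample unit impulse at
θ = ±π/2, r = 1 must correct phase by `fraction · π`, giving
`c = fraction · π · fs` with the default fraction 0.7.  An RK4 integrator is
available behind a flag.  If a strong kick drives `r` through the origin,
the state re-emerges at positive radius and antipodal angle (the polar-
coordinate reading of the planar flow).  Impulses are single samples; the
per-event phase kick is `c·s·r·sin θ / fs` (the same reading under which the
calibration is exact).

**Evoked responses.**  Each edge triggers a stereotyped waveform scaled by
the input magnitude; the response is the linear convolution of `s(t)` with
that kernel over lags −150..450 ms.  When working from response data the
kernel is estimated with a time-lagged ridge regression (temporal response
function), which unlike plain event averaging is unbiased under overlapping
responses at short inter-event intervals; the ridge penalty defaults to the
value minimising prediction error on a held-out final third of samples (the
regularisation scheme is otherwise unconstrained by the problem).  For
simulation, a synthetic kernel stands in for a data-derived one: a biphasic
deflection (positive lobe at 90 ms, negative at 160 ms, Gaussian lobes under
a Hann² taper that is identically zero outside 0–350 ms), whose FFT peaks at
4.8 Hz — an auditory-like transient with theta-dominant spectral content and
~350 ms duration.

**Noise.**  Both model outputs receive 1/f-shaped noise: Gaussian white
noise passed through an FIR filter least-squares-fit to a 1/f magnitude
target over 0.1–40 Hz (4 s of taps to resolve the low corner).  The
signal-to-noise ratio of 1/10 is read as a *power* ratio (noise RMS =
√10 × signal RMS), the conventional meaning of SNR; the amplitude reading
(noise 10× the signal RMS, i.e. 100× its power) is also supported via
`NoiseConfig.snr_domain` but buries the low-frequency phase structure of the
evoked model so deeply that its event-rate coherence peak is no longer a
local maximum — under the power reading all four qualitative model
signatures reproduce robustly.  To keep results independent of any one
noise draw, analyses run over a randomisation ensemble of 64 temporal-jitter
× 40 amplitude-noise realisations (2560 per model and condition; a desk-
scale 8 × 5 profile is provided and used by the bundled analyses), and the
analysis outputs are averaged across realisations.

## Synthetic stimuli

Real stimuli (a licensed radio-speech corpus and MEG recordings available
only on request) are replaced by a generative model of the landmark process
itself.  Its design is constrained by four joint statistics of natural read
speech at the two rates: a local-rate histogram with mean 5.7 Hz (SD
2.9) / 1.9 Hz (SD 1.0); a total event count of ~2100 in 6.5 / 19.5 minutes
(so the counting rate nearly equals the histogram mean); ~39% of events
with no successor within 500 ms (slow); and a spectral comb at the event
rate (without which the evoked model's low-frequency coherence component —
the phenomenon of interest — does not exist).

These constraints rule out renewal processes: for independent intervals, a
1/interval histogram with SD ≈ half its mean forces the product
E[f]·E[interval] ≥ ~1.2, while the printed count and rate give ~1.05, and
simulation confirms that matched renewal trains have no comb.  Syllabic
rhythm is instead modelled as locally quasi-periodic: within a prosodic
phrase (~12 beats) events sit on a beat grid with Gaussian jitter of 12% of
the period, occasionally an extra event falls between beats (P = 0.20 per
beat, at 25–75% of the interval — fast syllable runs, drawing smaller edge
magnitudes as reduced syllables do) and occasionally a beat is skipped
(P = 0.20 — hesitations; balancing insertions so the counting rate equals
the beat rate).  Phrase tempo varies across phrases with a symmetric
truncated-normal spread (CV floor 0.07), drawn by stratified (shuffled-
quantile) sampling so one stimulus realises the target marginal moments
quickly.  Utterances of 10–60 s are separated by 500–1100 ms silences.

The rate histogram is defined, as it would be measured from a real
stimulus, from event counts in windows of 1.5 mean periods tiled over
utterances (`instantaneous_rate_stats`); counting quantisation at this
resolution is what widens the histogram to SD ≈ mean/2 while the underlying
rhythm stays quasi-periodic.  Because the map from timing parameters to
these moments has no closed form, each train self-calibrates: tempo scale
and spread iterate (≤ 4 fixed-point steps on the same random stream) until
the realised moments match the spec — each generated stimulus, like the one
fixed stimulus set of a listening experiment, has the stated statistics.
Realised diagnostics at the defaults: ~2230 events per condition-length
train, P(gap > 0.5 s) ≈ 0.40 and P(gap > 1.04 s) ≈ 0.07–0.09 in the slow
condition.  Event magnitudes are log-normal clipped to (0, 1].

What the generator does *not* emulate: spectral structure of speech
(formants, pitch), lexical or phrase-final lengthening structure,
correlations between magnitude and local tempo, and multi-speaker
variability.  Passing tests therefore show that the *analysis machinery*
discriminates the mechanisms under realistic timing statistics — not that
it would do so under every corpus.

For end-to-end acoustic tests a waveform generator amplitude-modulates a
carrier with one asymmetric rise–decay bump per event (steepest rise at the
event time), so envelope extraction recovers exactly one peakRate and one
later peakEnv per well-separated event.

## Acoustic features

Envelope: rectification (full-wave by default; half-wave available since
the choice is not pinned down), zero-phase 4th-order Butterworth low-pass
at 10 Hz, downsampling to 100 Hz — in this order.  Derivative: first
difference × fs, left-aligned.  peakEnv are local maxima of the envelope,
peakRate local maxima of the positive part of the derivative (rises only).
The peak-prominence floor defaults to 5% of the series maximum: the
zero-phase low-pass itself imprints 1.5–3% pre/post-ringing on sharp rises,
so a 1% floor would triple-count clean edges.  Slowing is emulated by
linear time-axis resampling (duration × factor, amplitudes preserved,
derivative magnitudes × 1/factor); the pitch-synchronous machinery of true
audio slowing is out of scope.

## Time–frequency decomposition and phase statistics

Signals are decomposed into log-spaced bands (0.67–9 Hz, 0.1-octave steps;
38 bands) with zero-phase band-pass Butterworth filters plus Hilbert
transform; narrow (±0.1 octave) filters serve spectral analyses, wide
(±0.5 octave) filters temporal ones.  Filter orders are chosen (via
`buttord`) to meet ≤ 3 dB passband ripple and ≥ 24 dB stopband attenuation
*after* forward–backward filtering, with stopband edges 0.5 octave outside
the passband; 5 s reflection padding absorbs edge transients.

IEPC (inter-event phase coherence) is the resultant length of unit phasors
across event-locked epochs per band × time; CAC (cerebro-acoustic
coherence) is the resultant of the phase *difference* between a neural band
signal and the same-band speech envelope across each utterance, slow
utterances split into thirds to equate samples.  The chance level of IEPC
at finite N is the Monte-Carlo mean resultant of N uniform angles.
Significance of IEPC elevations uses 2D cluster permutation t tests against
the −400..−100 ms pre-event baseline: pixelwise one-sample t across
replicates, |t| above the two-sided p < 0.01 threshold, 4-connected
clusters scored by summed t, and a null of random per-replicate sign flips
(3000 permutations; the exchangeability scheme is the standard one for
one-sample designs).  Replicates are simulated subjects (independent
seeds), default 12.

Spectral profiles average IEPC over one post-event cycle at the condition's
rate (0–170 ms regular, 0–500 ms slow).  Profile peaks are interior local
maxima of the 3-band-smoothed profile with prominence above
max(2 × ensemble SD, 0.02).  Prominence — not exceedance of the pre-event
baseline — is the gate because in rhythmic input the phase at the event
rate is predictable both before and after an event, so the baseline there
is legitimately elevated and a baseline gate would suppress the genuine
event-rate peak; peak counting is a statement about profile shape.
Temporal profiles average IEPC over bands within half an octave of the
event rate and are compared with the chance level + 2 Monte-Carlo SD.
Isolated events for the temporal analysis have ≥ 200 ms to the preceding
and ≥ 1040 ms (two 1.9 Hz cycles for half an octave around the rate) to the
following event; the source material also prints 1000 ms/113 events
alongside 1040 ms/114 — both readings are reachable through parameters and
no count is hard-coded.  For the spectral analysis, events must have no
successor within one cycle of the condition's rate (500 ms slow, 170 ms
regular): a flat 500 ms rule retains ~39% of slow-condition events but
essentially none at the regular rate, so it cannot be what a regular-rate
analysis used.

The magnitude-quantile analysis splits events into five magnitude quantiles
(stable ties by event order) and averages theta (4–8 Hz) IEPC over one
cycle of each band (1/center) post-event.  The noise-robustness sweep
simulates the evoked model at noise levels 1–10× the response magnitude
(amplitude-domain by construction of the levels) and contrasts, across 20
simulations per level, the baseline-standardised post-event change in band
power versus IEPC, with paired two-sided t tests Bonferroni-corrected
across levels.

## Numerical and design notes

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical configuration + seed gives
  byte-identical outputs.
* Epoch sample indices round event times to the nearest sample at the
  consumer's rate; epochs that would leave the recording are dropped and
  counted.
* The ensemble averages analysis outputs (e.g. IEPC maps), not raw signals,
  matching the "analyse each realisation, then average" convention.
* Degenerate cases: a single distinct event magnitude maps to the upper
  scaling bound; constant profiles yield no peaks and undefined (NaN)
  correlations; `r` is an exact fixed point of the oscillator at 1 with no
  input.
* Desk-scale defaults used by the bundled analyses: 8 × 5 ensembles,
  120/300 s stimuli; the statistics stabilise at these sizes (the spectral
  peak structure is reproducible across seeds) while a full 64 × 40 run
  remains available via configuration.

## Known limitations

* The synthetic kernel is one plausible auditory transient; real
  MEG-derived kernels differ across subjects and conditions, and the exact
  location of the upper (response-shape) IEPC peak depends on it.
* The timing model's variance split (micro-timing vs tempo drift) is
  identified only indirectly by the joint statistics above; other splits
  satisfying the same constraints would shift the depth of the
  delta–theta valley.
* CAC is implemented and tested against its invariances and nulls, but the
  headline model comparison rests on IEPC, as the discriminating statistic.
* No sensor array is modelled: "sensors" reduce to channels, and
  topographic selection steps have no counterpart here.
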