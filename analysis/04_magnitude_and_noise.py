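"""Rate normalisation of edge magnitudes, model-vs-data fit, and noise robustness.

Three follow-up analyses on synthetic data:

1. Magnitude quantiles — theta IEPC per peakRate-magnitude quantile for a
   regular train and its threefold-stretched copy (magnitudes scaled to one
   third).  With rate-relative (min-max within condition) input scaling the
   quantile-quantile points fall on the diagonal: edge encoding is
   normalised to the contextual speech rate.
2. Model-data comparison — simulated "subjects" are fresh evoked-model
   responses; their delta IEPC time courses are correlated with both models'
   ensemble predictions and jointly regressed (data ~ OSC + ER).
3. Noise robustness — post-event theta power vs. theta IEPC effect sizes at
   noise levels 1-10x the response magnitude.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from edgetrack.containers import NoiseConfig, ResponseSeries
from edgetrack.evoked import run_randomized_ensemble
from edgetrack.oscillator import OscillatorParams, calibrate_coupling, simulate_oscillator
from edgetrack.stats import (
    compare_models,
    noise_robustness_sweep,
    quantile_iepc,
)
from edgetrack.synth import (
    EventTrainSpec,
    SyntheticKernelSpec,
    generate_event_train,
    generate_synthetic_kernel,
    generate_synthetic_response,
    stretch_event_train,
)
from edgetrack.tf import WIDE_HALF_WIDTH, epoch_phases, make_band_spec, select_events, tf_decompose

FS = 400.0


def _clean_response(events, kernel, seed, scaling="relative"):
    """Noiseless evoked response under rate-relative or absolute edge scaling."""
    from edgetrack.evoked import convolve_kernel
    from edgetrack.oscillator import build_event_input

    duration = float(events.times[-1]) + 1.0
    inp = build_event_input(
        events, fs=FS, duration=duration, jitter_sd=0.010, seed=seed
    )
    if scaling == "absolute":
        # replace the min-max-scaled impulses by the raw edge magnitudes
        inp.s[:] = 0.0
        idx = np.clip(np.round(events.times * FS).astype(int), 0, inp.s.size - 1)
        np.add.at(inp.s, idx, events.magnitudes)
    return convolve_kernel(inp, kernel)


def theta_quantiles(resp, events, noise_rms, seed):
    """Theta IEPC per magnitude quantile, under a *fixed* 1/f noise floor.

    The neural background does not scale with the stimulus, so the noise RMS
    is a constant of the recording, not of the condition; rate normalisation
    matters precisely because weaker absolute responses face the same floor.
    """
    from edgetrack.evoked import pink_noise

    noisy = ResponseSeries(
        data=resp.channel() + noise_rms * pink_noise(resp.n_samples, FS, seed=seed),
        fs=FS,
    )
    spec = make_band_spec(fmin=4.0, fmax=8.0, half_width=WIDE_HALF_WIDTH)
    tfm = tf_decompose(noisy, spec)
    ep = epoch_phases(tfm, events, window=(-0.5, 0.5))
    mags = events.magnitudes[ep.event_index]
    return quantile_iepc(ep, mags, band=(4.0, 8.0))


def delta_time_course(resp: ResponseSeries, events, rate: float):
    spec = make_band_spec(
        fmin=rate * 2**-0.25, fmax=rate * 2**0.25, half_width=WIDE_HALF_WIDTH
    )
    tfm = tf_decompose(resp, spec)
    selected = select_events(events, 0.2, 1.04)
    ep = epoch_phases(tfm, selected, window=(-0.5, 1.0))
    return np.abs(np.exp(1j * ep.phase).mean(axis=0)).mean(axis=0)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=str, default="results")
    ap.add_argument("--n-subjects", type=int, default=6)
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed)
    kernel = generate_synthetic_kernel(SyntheticKernelSpec(fs=FS))

    # --- 1. quantile analysis: regular vs threefold-stretched train
    regular = generate_event_train(
        EventTrainSpec(5.7, 2.9, 180.0, seed=int(rng.integers(2**31 - 1)))
    )
    slow = stretch_event_train(regular, 3.0)  # times x3, magnitudes x1/3
    seeds = [int(rng.integers(2**31 - 1)) for _ in range(6)]
    r_reg = _clean_response(regular, kernel, seeds[0])
    r_slow = _clean_response(slow, kernel, seeds[1])
    r_slow_abs = _clean_response(slow, kernel, seeds[2], scaling="absolute")
    # one noise floor for everything: sqrt(10) x the regular response RMS
    noise_rms = np.sqrt(10.0) * float(np.sqrt(np.mean(r_reg.channel() ** 2)))
    q_reg = theta_quantiles(r_reg, regular, noise_rms, seeds[3])
    q_slow = theta_quantiles(r_slow, slow, noise_rms, seeds[4])
    q_slow_abs = theta_quantiles(r_slow_abs, slow, noise_rms, seeds[5])
    qq = pd.DataFrame(
        {
            "quantile": np.arange(1, 6),
            "theta_iepc_regular": np.round(q_reg.values, 4),
            "theta_iepc_slow_normalised": np.round(q_slow.values, 4),
            "theta_iepc_slow_absolute": np.round(q_slow_abs.values, 4),
        }
    )
    qq.to_csv(out / "quantile_qq.csv", index=False)
    print("Theta IEPC by peakRate-magnitude quantile (regular vs 3x-slowed):")
    print(qq.to_string(index=False))
    print(
        "With rate-relative input scaling, slowed-speech phase alignment stays "
        "at or above the regular level in every quantile (slow responses are "
        "also free of overlap interference); feeding the absolute (one-third) "
        "magnitudes against the same neural noise floor depresses alignment "
        "across all quantiles.  Edge encoding behaves as normalised to the "
        "contextual speech rate.\n"
    )

    # --- 2. model-data comparison on delta IEPC time courses (slow speech)
    events = generate_event_train(
        EventTrainSpec(1.9, 1.0, 240.0, seed=int(rng.integers(2**31 - 1)))
    )
    duration = float(events.times[-1]) + 2.0
    noise = NoiseConfig(
        snr=0.1, jitter_sd=0.030, n_temporal_iters=4, n_amplitude_iters=4,
        seed=int(rng.integers(2**31 - 1)),
    )
    params = OscillatorParams(F=1.9, c=calibrate_coupling(0.7, FS), fs=FS)
    predictions = {}
    for name, predictor in (
        ("er", None),
        ("osc", lambda inp: ResponseSeries(
            data=simulate_oscillator(inp, params).pred, fs=FS)),
    ):
        predictions[name] = run_randomized_ensemble(
            events, kernel if name == "er" else None, noise,
            lambda r: delta_time_course(r, events, 1.9),
            fs=FS, duration=duration, predictor=predictor,
        )
    subjects = []
    for s in range(args.n_subjects):
        sim = generate_synthetic_response(
            events, kernel, NoiseConfig(snr=0.1, jitter_sd=0.030),
            fs=FS, seed=int(rng.integers(2**31 - 1)), duration=duration,
        )
        subjects.append(delta_time_course(sim.response, events, 1.9))
    fit = compare_models(np.stack(subjects), predictions)
    comp = pd.DataFrame(
        {
            "model": fit["models"],
            "mean_r": [np.nanmean(fit["correlations"][m]) for m in fit["models"]],
            "mean_beta": [fit["betas"][m].mean() for m in fit["models"]],
            "beta_t": [fit["beta_t"][m] for m in fit["models"]],
            "beta_p": [fit["beta_p"][m] for m in fit["models"]],
        }
    ).round(4)
    comp.to_csv(out / "model_data_fit.csv", index=False)
    print("Model fit to simulated subjects (delta IEPC time course, slow speech):")
    print(comp.to_string(index=False))
    print(
        "The evoked-response model carries the explained variance; the "
        "oscillator adds none for data generated by transient responses.\n"
    )

    # --- 3. power vs IEPC under increasing noise
    sweep_events = generate_event_train(
        EventTrainSpec(5.7, 2.9, 40.0, seed=int(rng.integers(2**31 - 1)))
    )
    sweep = noise_robustness_sweep(
        kernel, sweep_events, n_sims=20, seed=int(rng.integers(2**31 - 1))
    )
    tab = pd.DataFrame(
        {
            "noise_level": sweep["noise_levels"].astype(int),
            "iepc_dz": np.round(sweep["iepc_dz"], 3),
            "power_dz": np.round(sweep["power_dz"], 3),
            "paired_p_bonferroni": np.round(sweep["p_bonferroni"], 5),
        }
    )
    tab.to_csv(out / "noise_sweep.csv", index=False)
    print("Effect sizes of post-event theta change under increasing 1/f noise:")
    print(tab.to_string(index=False))
    print(
        "Phase coherence keeps a large effect size at noise levels where "
        "evoked power is no longer detectable."
    )


if __name__ == "__main__":
    main()
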