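"""Run both envelope-tracking models at both speech rates and compare their IEPC predictions.

The central analysis: oscillatory-entrainment and evoked-response models are
driven by the same synthetic peakRate trains through the randomisation
ensemble (temporal jitter x 1/f noise), and their inter-event phase
coherence is summarised as spectral profiles (one post-event cycle) and, for
slowed speech, delta-band time courses.  The two discriminating predictions
are reported: the number and location of spectral IEPC peaks, and whether
IEPC persists beyond one cycle after an isolated event.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from edgetrack.pipeline import PipelineConfig, run_full_comparison


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=str, default="results")
    ap.add_argument(
        "--full",
        action="store_true",
        help="Use the full 64x40 ensemble and full-length stimuli "
        "(default: 8x5 desk-scale profile).",
    )
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed, out_dir=args.out)
    if not args.full:
        cfg = dataclasses.replace(cfg.fast(), out_dir=args.out)
    report = run_full_comparison(cfg)

    rows = []
    for cond in ("regular", "slow"):
        for model in ("er", "osc"):
            res = report[cond][model]
            tp = res["temporal_profile"]
            row = {
                "condition": cond,
                "model": model,
                "n_spectral_events": res["spectral_map"].n_events,
                "n_peaks": len(res["peak_freqs"]),
                "peak_freqs_hz": ";".join(f"{f:.3f}" for f in res["peak_freqs"]),
            }
            if tp is not None:
                cycle = 1.0 / cfg.condition(cond)["rate"]
                t, v = tp["times"], tp["values"]
                thr = tp["baseline"] + 2 * tp["baseline_sd"]
                row["iepc_cycle1"] = round(float(v[(t >= 0) & (t <= cycle)].mean()), 3)
                row["iepc_cycle2"] = round(
                    float(v[(t >= cycle) & (t <= 2 * cycle)].mean()), 3
                )
                row["chance_threshold"] = round(float(thr), 3)
            rows.append(row)
    table = pd.DataFrame(rows)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "model_comparison.csv", index=False)
    print(table.to_string(index=False))

    er_peaks = report["slow"]["er"]["peak_freqs"]
    osc_peaks = report["slow"]["osc"]["peak_freqs"]
    print(
        f"\nSlow speech: the evoked-response model predicts {len(er_peaks)} IEPC "
        f"peaks ({', '.join(f'{f:.2f} Hz' for f in er_peaks)}) — the event rate "
        "plus the response shape — while the oscillator model predicts "
        f"{len(osc_peaks)} ({', '.join(f'{f:.2f} Hz' for f in osc_peaks)}). "
        "Temporally, the evoked model's delta IEPC returns to chance after one "
        "cycle whereas the oscillator's reverberates."
    )
    with open(out / "model_comparison.json", "w") as f:
        json.dump(
            {
                "slow_er_peaks_hz": [float(x) for x in er_peaks],
                "slow_osc_peaks_hz": [float(x) for x in osc_peaks],
                "seed": args.seed,
            },
            f,
            indent=2,
        )


if __name__ == "__main__":
    main()
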