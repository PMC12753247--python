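#!/usr/bin/env python
"""LFP pipeline per genotype: VEP cycle amplitudes and band power.

Reads the cohort bundles written by 01, preprocesses each LFP (300 Hz
low-pass, 1 kHz, 60 Hz notch), selects the strongest channel, derives
per-cycle windows from the averaged trace, measures VEP amplitudes, and
summarizes 4–8 / 8–12 / 12–30 / 30–40 Hz band power over 0.5–2.0 s.
Writes ``results/lfp_summary.csv``.
"""

import argparse
from dataclasses import replace
from pathlib import Path

import pandas as pd

from famosc import io
from famosc.lfp import (band_power_summary, derive_cycle_windows,
                        preprocess_lfp, select_channel_and_average,
                        vep_cycle_amplitudes)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundles", type=Path, default=Path("results/bundles"))
    ap.add_argument("--out", type=Path, default=Path("results/lfp_summary.csv"))
    args = ap.parse_args()
    rows = []
    for bundle in sorted(args.bundles.glob("*/familiar_lfp")):
        label = bundle.parent.name
        sess = io.read_session_bundle(bundle)
        clean = preprocess_lfp(sess.lfp, sess.lfp_rate)
        sess = replace(sess, lfp=clean, lfp_rate=1000.0)
        trace, chan = select_channel_and_average(sess)
        windows = derive_cycle_windows(trace, expected_n=5)
        amps = vep_cycle_amplitudes(trace, windows)
        power = band_power_summary(trace)
        row = {"group": label, "channel": chan,
               "n_cycles_found": len(windows.windows)}
        for i, a in enumerate(amps, start=1):
            row[f"vep_amp_cycle{i}_uv"] = round(float(a), 2)
        for (lo, hi), p in power.band_power.items():
            row[f"power_{lo:g}_{hi:g}hz"] = float(p)
        row["argmax_band"] = f"{power.argmax_band[0]:g}-{power.argmax_band[1]:g}"
        rows.append(row)
        print(f"{label}: channel {chan}, {len(windows.windows)} cycles, "
              f"VEP c1 {row.get('vep_amp_cycle1_uv', float('nan'))} uV, "
              f"argmax band {row['argmax_band']} Hz")
    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
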