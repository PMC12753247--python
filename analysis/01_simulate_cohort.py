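#!/usr/bin/env python
"""Simulate a three-genotype cohort and write it as session bundles.

Generates, per preset (WT-like, FX-like, CON-like): one familiar-stimulus
LFP + spiking recording, one 12-direction tuning recording, a Go/No-Go
training log, and a three-chamber trajectory — the full input set every
later driver consumes. Bundles land under ``results/bundles/<label>/``.
"""

import argparse
from pathlib import Path

from famosc import io, synthgen
from famosc.behavior import ChamberGeometry
from famosc.presets import DEFAULT_REGISTRY
from famosc.types import DIRECTIONS_DEG, TrialLayout


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/bundles"))
    ap.add_argument("--n-units", type=int, default=120)
    args = ap.parse_args()
    geom = ChamberGeometry.three_box()
    tuning_layout = TrialLayout(
        epoch_length=1.3, n_trials=20,
        directions=tuple(float(d) for d in DIRECTIONS_DEG))

    for k, (label, preset) in enumerate(sorted(DEFAULT_REGISTRY.items())):
        base = args.outdir / label
        seed = args.seed + 100 * k
        lfp_sess = synthgen.gen_lfp_session(preset, seed=seed)
        io.write_recording_bundle(base / "familiar_lfp", lfp_sess)
        spk = synthgen.gen_spike_session(preset, n_units=args.n_units,
                                         seed=seed + 1)
        io.write_recording_bundle(base / "familiar_spikes", spk)
        tun = synthgen.gen_spike_session(preset, tuning_layout,
                                         n_units=40, seed=seed + 2)
        io.write_recording_bundle(base / "tuning_spikes", tun)
        sessions = synthgen.gen_behavior_sessions(preset, seed=seed + 3)
        io.write_behavior_bundle(base / "gonogo", sessions, group=label)
        track = synthgen.gen_trajectory(preset, geom, duration_s=600.0,
                                        seed=seed + 4)
        io.write_trajectory_bundle(base / "threechamber", track, geom,
                                   group=label)
        n_spikes = sum(t.times.size for t in spk.spike_trains)
        print(f"{label}: LFP {lfp_sess.lfp.shape}, "
              f"{len(spk.spike_trains)} units / {n_spikes} spikes, "
              f"{len(sessions)} training days, "
              f"{track.positions.shape[0]} track frames -> {base}")


if __name__ == "__main__":
    main()
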