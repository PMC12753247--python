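#!/usr/bin/env python
"""Go/No-Go learning per genotype: TS curves, expert day, response times,
inter-trial touch activity, with the dispatch-gated group contrasts.

Writes ``results/learning_curves.csv`` (per day per genotype) and
``results/learning_stats.json`` (days-to-expert and touch contrasts).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from famosc import io
from famosc.behavior import (days_to_expert, intertrial_activity,
                             response_times, training_score)
from famosc.stats import GroupSample, build_report, compare_groups, report_json


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundles", type=Path, default=Path("results/bundles"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    rows, expert, touch_totals = [], {}, {}
    for bundle in sorted(args.bundles.glob("*/gonogo")):
        label = bundle.parent.name
        sessions = io.read_session_bundle(bundle)
        scores = [training_score(s) for s in sessions]
        day, censored = days_to_expert(scores)
        expert[label] = {"day": day, "censored": censored}
        touches = intertrial_activity(sessions)
        touch_totals[label] = list(touches.values())
        for s, ts in zip(sessions, scores):
            _, med = response_times(s)
            rows.append({"group": label, "day": s.session_day,
                         "training_score": round(ts, 3),
                         "median_rt_s": round(med, 3),
                         "intertrial_touches": s.intertrial_touches})
        print(f"{label}: expert on day {day}"
              f"{' (censored)' if censored else ''}, "
              f"final TS {scores[-1]:.2f}, "
              f"touches/day {touches}")
    df = pd.DataFrame(rows)
    args.outdir.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.outdir / "learning_curves.csv", index=False)

    comparisons = []
    if {"WT-like", "FX-like"} <= set(touch_totals):
        comparisons.append(compare_groups(
            GroupSample("FX-like", touch_totals["FX-like"]),
            GroupSample("WT-like", touch_totals["WT-like"])))
    report = build_report({"days_to_expert": expert}, comparisons)
    (args.outdir / "learning_stats.json").write_text(report_json(report))
    for c in comparisons:
        print(f"inter-trial touches {c.groups[0]} vs {c.groups[1]}: "
              f"{c.test} p={c.p_value:.3g} direction={c.effect_direction}")
    print(f"wrote {args.outdir / 'learning_curves.csv'} and "
          f"{args.outdir / 'learning_stats.json'}")


if __name__ == "__main__":
    main()
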