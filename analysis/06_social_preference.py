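#!/usr/bin/env python
"""Three-chamber social preference per genotype from the trajectory bundles.

Chamber time proportions over the full 10 min span, interaction-zone dwell
and chamber entries over the first 60 s. Writes
``results/social_preference.csv``.
"""

import argparse
from pathlib import Path

import pandas as pd

from famosc import io
from famosc.behavior import chamber_metrics


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundles", type=Path, default=Path("results/bundles"))
    ap.add_argument("--out", type=Path,
                    default=Path("results/social_preference.csv"))
    args = ap.parse_args()
    rows = []
    for bundle in sorted(args.bundles.glob("*/threechamber")):
        label = bundle.parent.name
        track, geom = io.read_session_bundle(bundle)
        m = chamber_metrics(track, geom, zone_span_s=60.0)
        p, z, e = m["chamber_proportions"], m["zone_dwell"], m["entries"]
        rows.append({
            "group": label,
            "prop_toy": round(p["toy"], 3),
            "prop_middle": round(p["middle"], 3),
            "prop_partner": round(p["partner"], 3),
            "zone_toy_60s": round(z["toy"], 3),
            "zone_partner_60s": round(z["partner"], 3),
            "entries_toy_60s": e["toy"], "entries_partner_60s": e["partner"],
        })
        print(f"{label}: partner {p['partner']:.2f} / toy {p['toy']:.2f} "
              f"of time; first-minute zone dwell partner "
              f"{z['partner']:.2f}, entries partner {e['partner']}")
    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out, index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
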