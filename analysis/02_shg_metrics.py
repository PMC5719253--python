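#!/usr/bin/env python
"""Quantify collagen maturity from the simulated SHG stacks.

For every stack: per-channel mu+sigma thresholds, per-slice area/density/
intensity, and the three F/B ratios; then compares F/B intensity between the
low-maturity ("nonIPF") and high-maturity ("IPF") groups with the
normality-gated two-group test.  Writes results/shg_metrics.csv.
"""

from pathlib import Path

import pandas as pd

from fibroquant import shg, stats

ROOT = Path(__file__).resolve().parents[1]
IN = ROOT / "scratch" / "simulated" / "shg"
RESULTS = ROOT / "results"


def main() -> None:
    paths = sorted(IN.glob("*.tif"))
    if not paths:
        raise SystemExit("no simulated stacks found; run 01_simulate_inputs.py first")
    frames = []
    for p in paths:
        stack = shg.read_stack(p)
        thr_f, thr_b, met_f, met_b, ratios = shg.analyse_stack(stack)
        frame = shg.metrics_frame(p.stem, thr_f, thr_b, met_f, met_b, ratios)
        frame.insert(1, "group", p.stem.split("_")[0])
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "shg_metrics.csv", index=False)

    for group, sub in table.groupby("group"):
        print(f"{group}: F/B intensity {sub['fb_intensity'].mean():.3f} "
              f"+/- {sub['fb_intensity'].std():.3f} (n={len(sub)})")
    a = table.loc[table["group"] == "nonIPF", "fb_intensity"].to_numpy()
    b = table.loc[table["group"] == "IPF", "fb_intensity"].to_numpy()
    res = stats.two_group_test(a, b)
    print(f"group comparison: {res}")
    print("higher F/B intensity in the high-maturity group reflects the "
          "forward channel's weighting toward mature fibrils")
    print(f"wrote {RESULTS / 'shg_metrics.csv'}")


if __name__ == "__main__":
    main()
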