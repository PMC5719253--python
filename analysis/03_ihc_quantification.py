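#!/usr/bin/env python
"""Quantify DAB staining in the simulated IHC tiles.

Unmixes each tile with the Haematoxylin/Eosin/DAB basis, builds the tissue
mask from the thresholded Eosin+DAB overlay, and reports percent tissue
surface area and density per subject and target, plus the LOX/LOXL1 and
LOX/LOXL2 ratios.  Writes results/ihc_quant.csv and results/ihc_ratios.csv.
"""

from pathlib import Path

import pandas as pd
import tifffile

from fibroquant import ihc

ROOT = Path(__file__).resolve().parents[1]
IN = ROOT / "scratch" / "simulated" / "ihc"
RESULTS = ROOT / "results"

EOSIN_OD_T = 0.05
DAB_OD_T = 0.05


def main() -> None:
    paths = sorted(IN.glob("*.tif"))
    if not paths:
        raise SystemExit("no simulated tiles found; run 01_simulate_inputs.py first")
    rows = []
    for p in paths:
        group, target, rep = p.stem.split("_")
        maps = ihc.unmix(tifffile.imread(p))
        tissue = ihc.tissue_mask(maps["eosin"], maps["dab"], EOSIN_OD_T, DAB_OD_T)
        q = ihc.quantify(maps["dab"], DAB_OD_T, tissue)
        rows.append({"subject": f"{group}_{rep}", "group": group, "target": target,
                     "percent_surface_area": q.percent_surface_area,
                     "density": q.density})
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "ihc_quant.csv", index=False)

    for (group, target), sub in table.groupby(["group", "target"]):
        print(f"{group:7s} {target:6s}: %area {sub['percent_surface_area'].mean():6.2f}, "
              f"density {sub['density'].mean():.4f}")

    ratios = ihc.ratio_table(table)
    ratios.to_csv(RESULTS / "ihc_ratios.csv", index=False)
    merged = ratios.merge(table[["subject", "group"]].drop_duplicates(), on="subject")
    for group, sub in merged.groupby("group"):
        col = "density_LOX_over_LOXL1"
        print(f"{group}: LOX/LOXL1 density ratio {sub[col].mean():.3f}")
    print(f"wrote {RESULTS / 'ihc_quant.csv'} and {RESULTS / 'ihc_ratios.csv'}")


if __name__ == "__main__":
    main()
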