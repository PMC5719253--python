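#!/usr/bin/env python
"""Simulate the study-style inputs for the downstream analysis scripts.

Creates, under scratch/simulated/:
  shg/       two-channel SHG stacks for a "non-IPF-like" group (low fibril
             maturity, m=0.45) and an "IPF-like" group (high maturity, m=0.65),
             4 stacks each
  ihc/       DAB-stained tiles, one per subject and target, with higher DAB
             levels in the IPF-like group for LOXL1/LOXL2 and lower for LOX
  afm/       force curves at the healthy (1.96 kPa) and fibrotic (16.52 kPa)
             parenchymal stiffness regimes, 35 curves x 3 areas each
  cohort/    a cohort table with the default two-factor structure

Ground truth is saved as YAML sidecars next to every file.
"""

from pathlib import Path

import numpy as np

from fibroquant import afm, shg
from fibroquant import synthetic as syn

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "simulated"
SEED = 20170501

SHG_SHAPE = (64, 64, 16)
SHG_GROUPS = {"nonIPF": 0.45, "IPF": 0.65}
IHC_DAB = {  # (group, target) -> mean DAB concentration of stained blobs
    ("nonIPF", "LOX"): 0.18, ("IPF", "LOX"): 0.10,
    ("nonIPF", "LOXL1"): 0.08, ("IPF", "LOXL1"): 0.16,
    ("nonIPF", "LOXL2"): 0.08, ("IPF", "LOXL2"): 0.14,
}
AFM_GROUPS = {"healthy": 1.96, "fibrotic": 16.52}


def main() -> None:
    rng_offset = 0

    shg_dir = OUT / "shg"
    shg_dir.mkdir(parents=True, exist_ok=True)
    for group, m in SHG_GROUPS.items():
        for i in range(4):
            seed = SEED + rng_offset
            rng_offset += 1
            truth = syn.SHGGroundTruth(
                segments=syn.random_segments(12, SHG_SHAPE, maturity=m, seed=seed),
                background_level=40.0, noise_sd=15.0, seed=seed,
            )
            stack = syn.gen_shg_stack(truth, SHG_SHAPE)
            shg.write_stack(stack, shg_dir / f"{group}_{i}.tif")
            syn.write_truth_yaml(truth, shg_dir / f"{group}_{i}.truth.yaml")
    print(f"SHG: wrote {2 * 4} stacks (maturity {SHG_GROUPS}) to {shg_dir}")

    ihc_dir = OUT / "ihc"
    ihc_dir.mkdir(exist_ok=True)
    for (group, target), level in IHC_DAB.items():
        for i in range(3):
            seed = SEED + rng_offset
            rng_offset += 1
            maps = syn.random_concentration_maps((96, 96), seed=seed,
                                                 max_concentration=level)
            # eosin background marks the tissue everywhere
            maps["eosin"] = np.maximum(maps["eosin"], 0.12)
            truth = syn.IHCGroundTruth(concentration_maps=maps, seed=seed)
            import tifffile
            tifffile.imwrite(ihc_dir / f"{group}_{target}_{i}.tif",
                             syn.gen_ihc_image(truth))
            syn.write_truth_yaml(truth, ihc_dir / f"{group}_{target}_{i}.truth.yaml")
    print(f"IHC: wrote {len(IHC_DAB) * 3} tiles to {ihc_dir}")

    afm_dir = OUT / "afm"
    afm_dir.mkdir(exist_ok=True)
    for group, E_true in AFM_GROUPS.items():
        peak = afm.hertz_force(4.0, E_true, 2.5, 0.4)
        for area in range(3):
            for i in range(35):
                seed = SEED + rng_offset
                rng_offset += 1
                truth = syn.CurveGroundTruth(
                    E_true=E_true, contact_point=2.0, baseline_slope=0.02 * peak,
                    noise_sd=0.02 * peak, seed=seed,
                )
                curve = syn.gen_force_curve(truth)
                afm.write_curve(curve, afm_dir / f"{group}_a{area}_c{i:02d}.csv")
    print(f"AFM: wrote {2 * 3 * 35} curves ({AFM_GROUPS} kPa) to {afm_dir}")

    cohort_dir = OUT / "cohort"
    cohort_dir.mkdir(exist_ok=True)
    truth = syn.default_cohort_truth(
        n_per_group=100, seed=SEED,
        group_shift={"non-IPF": np.zeros(4), "IPF": np.array([1.0, 1.0, 0.0, 0.0])},
    )
    table = syn.gen_cohort(
        truth, variables=["fb_intensity", "loxl1_density",
                          "loxl2_density", "lox_density"])
    table.to_csv(cohort_dir / "cohort.csv", index=False)
    syn.write_truth_yaml(truth, cohort_dir / "cohort.truth.yaml")
    print(f"Cohort: wrote {len(table)} subjects to {cohort_dir}")


if __name__ == "__main__":
    main()
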