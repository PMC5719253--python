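#!/usr/bin/env python
"""Fit the simulated force curves with the Hertz sphere model.

Recovers Young's modulus per curve, aggregates median/IQR per stiffness
group (healthy 1.96 kPa vs fibrotic 16.52 kPa generators), and compares the
groups with Kruskal-Wallis + Dunn.  Writes results/afm_fits.csv and
results/afm_summary.csv.
"""

from pathlib import Path

import pandas as pd

from fibroquant import afm

ROOT = Path(__file__).resolve().parents[1]
IN = ROOT / "scratch" / "simulated" / "afm"
RESULTS = ROOT / "results"


def main() -> None:
    paths = sorted(IN.glob("*.csv"))
    if not paths:
        raise SystemExit("no simulated curves found; run 01_simulate_inputs.py first")
    rows = []
    for p in paths:
        group, area, _ = p.stem.split("_")
        (curve,) = afm.parse_curves(p)
        fit = afm.fit_curve(curve)
        rows.append({"curve": p.stem, "group": group, "area": area,
                     "E": fit.E, "contact_point": fit.contact_point,
                     "converged": fit.converged})
    fits = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    fits.to_csv(RESULTS / "afm_fits.csv", index=False)

    summary = afm.aggregate(fits, by="group").summary
    summary.to_csv(RESULTS / "afm_summary.csv", index=False)
    for _, r in summary.iterrows():
        print(f"{r['group']:9s}: median E = {r['median']:6.2f} kPa "
              f"[IQR {r['q1']:.2f}-{r['q3']:.2f}], n = {r['n']}, "
              f"failed fits = {r['n_failed']}")

    groups = {g: sub["E"].to_numpy() for g, sub in fits.groupby("group")}
    report = afm.kruskal_dunn(groups)
    print(f"Kruskal-Wallis H = {report['H']:.2f}, p = {report['p']:.3g}")
    print(report["pairwise"].to_string(index=False))
    print(f"wrote {RESULTS / 'afm_fits.csv'} and {RESULTS / 'afm_summary.csv'}")


if __name__ == "__main__":
    main()
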