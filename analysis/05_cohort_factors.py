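#!/usr/bin/env python
"""Integrate the cohort variables: correlations, factor analysis, group scores.

On the simulated cohort (two planted relationship groups; the IPF group
shifted on the first factor's variables): pairwise Pearson correlations with
Benjamini-Hochberg adjustment, Kaiser eigenvalue >= 1 factor count, PAF +
promax loadings, and loading-weighted group scores compared between groups.
Writes results/cohort_correlations.csv, results/factor_model.yaml and
results/group_scores.csv.
"""

import warnings
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fibroquant import stats

ROOT = Path(__file__).resolve().parents[1]
IN = ROOT / "scratch" / "simulated" / "cohort" / "cohort.csv"
RESULTS = ROOT / "results"


def main() -> None:
    if not IN.exists():
        raise SystemExit("no simulated cohort found; run 01_simulate_inputs.py first")
    table = pd.read_csv(IN)
    variables = [c for c in table.columns if c not in ("subject", "group")]
    RESULTS.mkdir(exist_ok=True)

    rows = []
    for a, b in combinations(variables, 2):
        r, r2, p = stats.correlate(table, a, b)
        rows.append({"var_a": a, "var_b": b, "r": r, "r_squared": r2, "p": p})
    corr = pd.DataFrame(rows)
    corr["p_bh"] = stats.bh_adjust(corr["p"].to_numpy())
    corr.to_csv(RESULTS / "cohort_correlations.csv", index=False)
    print("pairwise correlations (pooled across groups):")
    print(corr.round(4).to_string(index=False))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = stats.fit_factor_model(table, n_factors="auto")
    print(f"\neigenvalues: {np.round(model.eigenvalues, 3).tolist()}")
    print(f"relationship groups (eigenvalue >= 1): {model.n_factors}")
    print("promax pattern (variables x factors):")
    print(pd.DataFrame(model.pattern, index=variables,
                       columns=[f"factor_{j+1}" for j in range(model.n_factors)]
                       ).round(3).to_string())
    (RESULTS / "factor_model.yaml").write_text(yaml.safe_dump({
        "variables": variables,
        "eigenvalues": model.eigenvalues.tolist(),
        "n_factors": model.n_factors,
        "pattern": model.pattern.tolist(),
        "communalities": model.communalities.tolist(),
        "factor_correlations": model.factor_correlations.tolist(),
    }, sort_keys=False))

    gs = stats.group_scores(table, model)
    gs.scores.to_csv(RESULTS / "group_scores.csv", index=False)
    print("\ngroup scores (loading-weighted averages of z-scored variables):")
    for j in range(model.n_factors):
        col = f"factor_{j + 1}"
        a = gs.scores.loc[gs.scores["group"] == "non-IPF", col].to_numpy()
        b = gs.scores.loc[gs.scores["group"] == "IPF", col].to_numpy()
        res = stats.two_group_test(a, b)
        print(f"  {col}: non-IPF {a.mean():+.3f} vs IPF {b.mean():+.3f} -> {res}")
    print(f"wrote correlation, factor-model and score tables to {RESULTS}")


if __name__ == "__main__":
    main()
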