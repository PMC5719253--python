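# fibroquant

Quantification of fibrillar-collagen remodelling and tissue mechanics in lung
fibrosis. Idiopathic pulmonary fibrosis (IPF) stiffens the lung's
extracellular matrix as lysyl-oxidase enzymes (LOX, LOXL1, LOXL2) cross-link
fibrillar collagen; this package implements the measurement pipeline used to
characterise that remodelling, for researchers working with second-harmonic-
generation (SHG) microscopy, brightfield immunohistochemistry (IHC), and AFM
micro-indentation of tissue sections.

Four analysis stages, each importable on its own, plus synthetic-data
generators so the whole pipeline is testable without tissue images:

* **`fibroquant.shg`** — forward/backward SHG collagen-maturity metrics. A
  per-channel threshold `T = mu + sigma` (mean and population s.d. of the
  whole 3-D image) separates signal from background; each z-slice yields
  *area* (voxels above `T`), *density* (their mean intensity) and *intensity*
  (area x density); the stack means give the F/B ratios. Higher F/B intensity
  = thicker, more mature, more organized fibrils.
* **`fibroquant.ihc`** — Ruifrok–Johnston colour deconvolution. Per pixel,
  `OD_c = -log10((I_c + 1/255)/255)` is unmixed through the inverse of the
  unit stain-vector matrix (Haematoxylin/Eosin/DAB); the tissue mask is the
  thresholded Eosin+DAB overlay; outputs are *percent tissue surface area*
  (100 · DAB area / tissue area) and *density* (mean DAB OD over tissue).
* **`fibroquant.afm`** — Hertz sphere-contact fitting,
  `F = (4/3) · E/(1−ν²) · √R · δ^{3/2}` (E in kPa, lengths in µm, force in
  nN). The contact point is profiled out by least squares over a candidate
  grid with continuous refinement; Kruskal–Wallis + Dunn compares groups.
* **`fibroquant.stats`** — cohort integration: D'Agostino–Pearson-gated
  t / Mann–Whitney tests, Pearson correlations, principal-axis factoring of
  the correlation matrix with promax rotation, Kaiser eigenvalue ≥ 1 factor
  count, and loading-weighted "relationship-group" scores.

## Worked example

Recover a known stiffness from a synthetic indentation curve:

```python
from fibroquant import afm, synthetic as syn

truth = syn.CurveGroundTruth(E_true=16.52, contact_point=2.0, noise_sd=0.0)
fit = afm.fit_curve(syn.gen_force_curve(truth))
print(f"E = {fit.E:.2f} kPa, contact at {fit.contact_point:.3f} um")
```

prints `E = 16.52 kPa, contact at 2.000 um` — the fitted Young's modulus
matches the generating value (the fibrotic-parenchyma stiffness regime), and
the contact point lands on the true 2 µm.

The same works from the shell:

```sh
fibroquant simulate afm --seed 1 --out sim/
fibroquant afm fit --in sim/ --out fits.csv
# curve_000: E = 16.52 kPa (contact at 2.000 um)
```

The numbered scripts under `analysis/` run the full study-style workflow on
simulated cohorts (`01_simulate_inputs.py` → `05_cohort_factors.py`), writing
tables under `results/`. For example `04_afm_stiffness.py` reports

```
fibrotic : median E =  16.55 kPa [IQR 16.44-16.68], n = 105, failed fits = 0
healthy  : median E =   1.96 kPa [IQR 1.95-1.98], n = 105, failed fits = 0
Kruskal-Wallis H = 156.75, p = 5.79e-36
```

— 105 noisy curves per group (35 per area, three areas), medians within 0.2%
of the generating moduli, and an unambiguous group separation.

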