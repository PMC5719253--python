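# Methods

This note documents the models, conventions and numerical choices behind each
analysis stage, what the synthetic generators do and do not emulate, and the
design decisions taken where the underlying measurement conventions were
genuinely open.

## SHG forward/backward metrics (`fibroquant.shg`)

**Model.** Fibrillar collagen emits frequency-doubled light in both the
forward and backward directions; thick/mature, well-organized fibrils emit
predominantly forward, thin/immature, disorganized fibrils predominantly
backward. Ratios of forward to backward summary statistics therefore index
fibril maturity.

**Thresholding.** The background threshold for each channel is `T = mu +
sigma`, with `mu` and `sigma` computed over *all* voxels of the 3-D channel,
background included, and `sigma` the population standard deviation (ddof=0).
Whether the original workflow used the population or sample form is
unknowable from the outside; the two differ by `O(1/N)` on stacks of tens of
thousands of voxels. "Above threshold" is strict (`>`): ties at `T` count as
background, so a constant image has zero signal area.

**Per-slice metrics and averaging.** For each z-slice: `area` = count of
above-threshold voxels, `density` = their mean intensity, `intensity` =
`area x density` (exact by construction). Slices with zero area contribute 0
to the area and intensity means but are excluded from the density mean — the
mean intensity of an empty voxel set is undefined, and imputing 0 would bias
the density statistic downward on sparse stacks. Ratios are taken of the
stack means, not means of per-slice ratios (averaging first, then forming the
ratio). Thresholds are computed independently per channel because the two
detectors have independent gains; a consequence worth knowing is that
F/B area and F/B intensity are invariant to a joint rescaling of both
channels, while F/B density scales linearly with a forward-only rescaling.

**Region sampling.** Imaging regions are drawn uniformly without replacement
from a rows x cols tile grid with a seeded generator (10x10 grids with 3
regions for tissue-scale samples, 5x5 for smaller decellularized pieces).

## IHC colour deconvolution (`fibroquant.ihc`)

**Model.** Beer–Lambert absorption: per pixel and RGB channel,
`OD_c = -log10((I_c + eps)/I0)` with `I0 = 255` (8-bit brightfield
convention) and `eps = 1/255` to avoid `log 0`. The OD vector is a linear
mixture of unit stain vectors; unmixing multiplies by the basis inverse and
clips negative concentrations to zero.

**Stain basis.** The default is the published Ruifrok–Johnston
Haematoxylin/Eosin/DAB matrix (rows normalized to unit length). Studies
typically optimize vectors per staining batch; the basis is therefore
overridable everywhere (`StainBasis`, CLI `--basis file.yaml`). Absolute
density values depend on the basis and thresholds, so only within-batch
comparisons are meaningful.

**Quantification.** The tissue mask is the union of thresholded Eosin and DAB
maps (whitespace excluded); `percent_surface_area` = 100 · (DAB pixels above
threshold within tissue) / tissue pixels, and `density` = mean DAB OD over
all tissue pixels. "Whole tissue" is taken as the tissue mask rather than the
whole frame because whitespace area varies with sectioning, which would make
a frame-wide mean incomparable across slides. Default OD thresholds use the
triangle method on each channel's histogram (unimodal background), also
overridable as fixed values.

## AFM Hertz fitting (`fibroquant.afm`)

**Model.** Rigid sphere of radius `R` on an elastic half-space:
`F(δ) = (4/3) · E/(1−ν²) · √R · δ^{3/2}`, `δ = z − z0`. Units are fixed to
E in kPa, lengths in µm, forces in nN; the bridge is `1 kPa·µm² = 1 nN`
(declared once as `KPA_UM2_TO_NN`). Poisson ratio defaults to 0.4 (soft
hydrated tissue), probe radius to 2.5 µm; both are per-curve metadata.

**Estimation.** For a fixed contact point the model
`F = a + b·z + c·max(z−z0, 0)^{3/2}` is linear, so `(a, b, c)` are solved
exactly by least squares — the baseline (drift) and the Hertz term are
estimated jointly, and `z0` is profiled out: a coarse grid over sample
positions picks the best candidate, then bounded scalar minimisation refines
`z0` continuously between its grid neighbours. The selection objective is the
*mean* squared residual, `RSS/(n−3)`, not raw RSS: the fitted window size
varies with the candidate (see next paragraph), and raw RSS would
systematically favour late contact points that discard data. A negative Hertz
coefficient (possible on pure-noise curves) triggers a baseline-only refit,
so the reported modulus is never negative; curves too short to fit return
`converged=False` with a message, never a silent zero.

**Indentation cap.** The fit uses `δ ≤ max_indentation_fraction` (default
0.5) of the post-contact range. A 10-µm ramp on a 10-µm cryosection indents
deep enough for substrate stiffening to contaminate the tail of the curve;
capping the fitted depth mitigates this. No finite-thickness (bottom-effect)
correction is applied by default, matching the plain sphere model; the cap is
configurable for users who want the full range.

**Group comparison.** Kruskal–Wallis omnibus plus Dunn's pairwise z tests on
pooled ranks with tie correction; the family-wise adjustment is the classical
Bonferroni scheme over all pairwise comparisons. Degenerate input (all values
identical) reports p = 1 rather than failing. The asymptotic p is
cross-checked against a permutation oracle in the test suite.

## Cohort statistics (`fibroquant.stats`)

**Two-group tests.** Groups are tested for normality with the
D'Agostino–Pearson omnibus test; both normal → unpaired two-tailed t-test,
otherwise Mann–Whitney U. The omnibus test needs n ≥ 8, so smaller groups
take the nonparametric branch unconditionally — relevant because tissue
cohorts of 7–10 subjects sit exactly at this edge. The branch taken is
recorded in the result and is a pure function of the gate.

**Correlations.** Pearson r pooled across groups (pairwise-complete), with
`R² = r²` and two-tailed p; correlation families can additionally be
Benjamini–Hochberg adjusted (`bh_adjust`), reported alongside raw p.

**Principal-axis factoring.** Communalities start at squared multiple
correlations, the reduced correlation matrix is eigen-decomposed, and the top
k loadings update the communalities, iterating to `1e-6` (max 1000
iterations). Heywood cases are clipped to 1 with a warning. One caveat
deserves emphasis: a 2-factor model on 4 variables has negative degrees of
freedom, so a continuum of solutions fits the correlation matrix exactly; the
communality iteration then creeps along this flat ridge and may never meet a
tight tolerance even though the *loading subspace* stabilises within tens of
iterations. If the iteration cap is reached while the per-step change is
below `1e-3` (the scale of the classical SPSS criterion), the current
solution is returned with a warning; a genuinely diverging iteration raises
with the full change trace. Rotation then resolves the remaining
indeterminacy toward simple structure, which is why recovery of planted
loadings is reliable in this regime.

**Promax rotation.** Varimax (Kaiser-normalised) pre-rotation, then the
Hendrickson–White power-target transform with kappa = 4 (conventional
default), returning the oblique pattern matrix and factor correlations.
Factors are oriented so the dominant loading is positive. The implementation
is cross-checked against `statsmodels`' promax in the test suite.

**Factor count and group scores.** The number of "relationship groups" is the
Kaiser criterion — correlation-matrix eigenvalues ≥ 1, boundary inclusive.
Per-subject group scores are weighted averages of z-scored variables with
weights `|pattern loading| / sum of |loadings|` within each factor, computed
on listwise-complete subjects only. This weighting is a stipulated
convention: "strength of contribution" does not pin down a formula, and
absolute normalized pattern loadings on standardized variables is the
simplest choice that (a) reduces to a plain mean under equal loadings,
(b) selects a single variable under a one-hot loading vector, and (c) is
insensitive to the arbitrary sign of a factor.

## Synthetic generators (`fibroquant.synthetic`)

What each generator emulates, and the fixed defaults:

* **SHG stacks.** Fibril segments are hard cylinders with a linear one-voxel
  anti-aliased edge (occupancy 1 inside radius `r`, falling to 0 at `r+1`) —
  simple enough that a voxel's expected value is checkable by hand. A
  segment's emission is split `m : (1−m)` between the forward and backward
  channels, so total emission is independent of maturity; with equal gains,
  background 0 and no noise, the F/B intensity ratio equals `m/(1−m)`
  exactly (4.0 at m = 0.8). Noise is additive Gaussian clipped at zero —
  adequate for threshold-behaviour tests without modelling detector physics.
  Defaults: gains 2000 a.u., background 50 a.u., noise s.d. 10 a.u.
* **IHC tiles.** Transmitted light `I0 · 10^(−Σ c_s · basis_s)`, rounded to
  the 8-bit grid; zero-concentration pixels are white. Random maps are
  Gaussian-smoothed noise scaled to a per-stain ceiling of 0.2 OD. That
  ceiling is an analytic choice, fixed before any testing: at 0.2 on all
  three stains the most absorbing channel (green, column sum 2.26 of the
  basis) transmits ≥ 90 counts, so 8-bit rounding perturbs a channel's OD by
  at most `0.504/(90·ln 10) ≈ 0.0024`, and the basis inverse amplifies a
  worst-case OD error by at most its column L1 norm (≤ 2.62), keeping the
  recovered-concentration error under `0.0064 < 2/255`.
* **Force curves.** Linear baseline drift plus the Hertz term past the
  contact point, additive Gaussian noise in nN. Defaults mirror the
  acquisition geometry: R = 2.5 µm, ν = 0.4, 10-µm ramp, 500 samples,
  contact at 2 µm. "1% noise" conditions are realised as noise s.d. = 1% of
  the curve's peak fitted force.
* **Cohorts.** `x = shift[group] + Λf + e` with standard-normal factors and
  independent residuals of variance `uniqueness`. The default plants two
  relationship groups across four variables — loadings
  `[[.8,0],[.7,0],[0,.8],[0,.7]]`, uniqueness 0.3 — mirroring the two-group
  structure the factor analysis is meant to detect while remaining fully
  synthetic.

**What passing tests do not show.** The generators omit the physics that
makes real data hard: SHG phase-matching, polarization and PSF blur;
slide-scanner vignetting, batch-to-batch stain variation and nuclear
morphology; AFM cantilever dynamics, adhesion and viscoelastic creep;
non-Gaussian biological covariance. Parameter recovery here validates the
*estimators* (correct formulas, correct inversion, correct bookkeeping), not
robustness to those effects. Absolute IHC densities and study-level tissue
values are additionally unreproducible because the original per-subject
images, optimized stain vectors and thresholds are not published.

## Problem sizes

Test and acceptance runs use desk-scale inputs chosen as the smallest sizes
at which each property is cleanly measurable: 16³ stacks for oracle
equivalence, 32x32 tiles for round-trip bounds, 500-point curves (the ramp's
natural sampling), 100-curve Monte-Carlo batches, and cohorts of 200–500
subjects for factor recovery.
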