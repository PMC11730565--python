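# Methods

## Index computation

All indices are computed **per site**. Field studies report per-sample class
distributions ("x % of samples in class y"), so the site-level value is the
primitive; any averaging over sites is left to the caller.

* `Cf = Ci/Cb` and `PI = Ci/Si` share one implementation: both this package
  and the studies it serves source `Cb` and `Si` from the same reference
  compilation, making the two indices numerically identical. Defaults
  (mg kg⁻¹): As 5, Cd 0.3, Co 10, Cr 80, Cu 25, Ni 20, Pb 17, Sb 0.5,
  Mn 530, after Reimann & de Caritat.
* The Nemerow index is implemented in its standard radical form
  `Pn = √((mean(PI)² + max(PI)²)/2)` — the only form for which Pn = 1 at
  exact background and `max/√2 ≤ Pn ≤ max` holds.
* `Igeo = log2(Ci/(1.5·Cb))`; the 1.5 factor absorbs lithogenic background
  variability. A zero (censored) concentration has no Igeo: the entry is
  flagged missing rather than imputed. Optionally, values below a declared
  detection limit can be substituted by DL/2 before computation (off by
  default; censoring treatment is a study-level decision).
* `PLI` is the geometric mean of Cf, computed in log space; it is undefined
  (flagged missing) when any contributing Cf is zero.
* Composites (mCd, Pn, RI, PLI) over a site with missing elements use the
  per-site available subset of the requested elements; `n_elements` records
  the count actually used, and sites with incomplete coverage are counted in
  the log. Silent imputation would bias composites; dropping the site
  entirely would discard the information the remaining elements carry.

## Classification

Class boundaries follow the published interpretation tables literally:
intervals are lower-closed (a value at a cut belongs to the
more-contaminated class, so Cf = 1 is "Moderate" and Eir = 30 "moderate
risk") except where a table prints a closed upper bound (all Pn cuts;
Igeo ≤ 0), which is honoured. Where printed rows overlap at a boundary
(Igeo at 0) the less-contaminated class wins. PLI's "baseline" class is the
exact value 1 only — on continuous data it is effectively unobserved, which
matches the binary polluted/not-polluted reporting such data supports. No
tolerance band is applied at any boundary: classification operates on the
raw double.

### RI recalibration

Hakanson's RI grades (150/300/600) presuppose a pollutant suite with
ΣTr = 133. For an arbitrary suite the first bound is
`round₁₀(ΣTr · 150/133)` with ties rounding up, and each subsequent bound
doubles the previous. The exact ratio 150/133 is used internally rather than
the 2-decimal 1.13: both anchors are preserved (70 → 78.95 → 80;
133 → 150 → 150) without compounding rounding error. If the rounded bound
would be zero (ΣTr ≲ 4.4, below any practical suite) the unrounded value is
kept so the scheme stays valid. Single-element Eir bounds (30/60/120/240)
are fixed by the most-toxic-element argument and are **not** recalibrated.

## Raster sampling

Point-in-cell lookup uses the half-open `[left, right) × (top, bottom]`
convention with a top-left origin; extraction is nearest-cell (no
interpolation — the rasters are already smooth interpolated products), with
an optional k×k window mean. Nodata and outside-extent lookups propagate to
explicit missing values and are counted in an extraction report, never
coerced to zero. Rasters are stored in a plain-text grid format (header:
ncols, nrows, origin, cellsize, nodata, crs; then rows, northernmost
first); one element per raster.

## Synthetic scenario generator

The generator emulates the statistical situation of a mining district
assessed twice — by a dense field campaign and by a coarse open-data map —
so the whole pipeline is testable at desk scale.

**True fields.** Per element,
`ln C(x,y) = ln m + σ·Z(x,y) + Σ_h ln(p_h)·exp(−d_h²/2ℓ_h²)`, with `m` the
scene background median, `Z` a unit-variance Gaussian field (Gaussian-filter
correlated, then renormalised to mean 0 / variance 1 so the field median
equals the configured background), and plumes given by a peak enrichment
factor `p_h` (dimensionless multiplier at the centre) decaying on the log
scale with length `ℓ_h`. Log-additive plumes keep concentrations positive
and reproduce the right-skewed distributions of real geochemical data.

**Defaults (chosen once as a realistic mineralized district, then frozen).**
6 × 8 km scene (48 km², the size class of a detailed mine survey);
σ = 0.5 (log scale), correlation length 400 m, 50 m fine grid; field
campaign on a 400 m grid (⌊W/s⌋·⌊H/s⌋ = 300 sites) with 15 % multiplicative
measurement noise (mean-one log-normal); three As/Sb/Cu/Pb-rich plumes
(peak factors 6–30, lengths 0.9–1.3 km). The scene's local background
medians are 1.2–3× the reference values (a mineralized district), while the
**regional** background seen by the sparse survey outside the scene is set
to 0.6× the reference values (continental medians sit below soil reference
values). This local/regional contrast is what makes the comparison
informative: a sparse survey samples almost exclusively the regional
baseline.

**Open-data emulation.** Survey sites are a homogeneous Poisson draw
(default 1 per 200 km², the density behind 1 km continental topsoil maps)
over the scene buffered by 3× the mean survey spacing, so even a scene with
zero interior points interpolates from outside. In-scene sites read the
true field; outside sites draw from the regional log-normal plus plume
tails. Values are interpolated to the coarse grid (default 1 km) by
inverse-distance weighting (power 2, 4 neighbours). IDW stands in for the
kriging used by real map products: the mechanism under study depends on
smoothing plus sparsity, not the interpolation variant, and IDW keeps the
generator deterministic and dependency-light. With zero survey points the
raster falls back to the regional median.

At the default density the expected number of survey points inside the
scene is 0.24, so most random seeds place none there and the open-data
raster misses both the district-wide enrichment and the plumes; the
occasional seed that does land a point in the scene captures part of the
signal and the success rates jump — the seed-to-seed variability is the
sampling reality being modelled, not noise to be suppressed. Statistical
claims are therefore evaluated on seed averages (10–12 seeds), and the
cell-size comparison is paired per seed (the survey draw is independent of
the output cell size).

**What the generator does not emulate:** real kriging models and their
covariates, detection-limit censoring of survey analytics, land-use-
stratified survey siting, anisotropic or non-Gaussian plume geometry, and
any specific real district's geochemistry. Passing tests show the pipeline
reproduces the *mechanism* (sparse smoothed maps under-classify local
contamination; density, not cell size, controls accuracy); they do not
validate any particular real-world map product.

## Concordance

Success rate = 100 × diagonal/total of the confusion matrix with field
samples as reference rows; misclassification is its exact complement.
Sites unclassified in either source (missing index values) are excluded
from the matrix and counted in the log. Cohen's kappa is provided as a
supplementary chance-corrected statistic only. Percentages are serialised
to 2 decimals.

## Problem sizes and determinism

Default test/acceptance runs use the 300-site scenario on a 120 × 160 fine
grid; a full scenario plus both assessments and the concordance report
takes well under a second, and the seed-averaged properties (12 seeds ×
3 densities) a few seconds. Every stochastic quantity derives from
`numpy.random.default_rng` seeded by (scenario seed, stage, element), so
identical configurations are bit-reproducible across runs and platforms.

## Known limitations

* Single shared CRS (string equality); no reprojection or geodetic support.
* No enrichment factor, bioavailability or dose models.
* The IDW open-data emulator honours an in-scene survey point more strongly
  than a continental kriging model with a nugget would; at sparse density
  this makes "lucky seed" success rates an upper bound on what a real map
  product would achieve.
* PLI's point-class at exactly 1 is unreachable on continuous data by
  construction.
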