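# Methods

This note documents the models, conventions and design choices behind
`guildscape`, in the order the analysis chain runs.

## 1. Habitat geometry and rasterization

Habitat maps arrive as polygon and line layers with integer class codes.
Lines (hedgerows, tree rows, water courses) are buffered to polygons of
half-width 5 m (round caps) before rasterization so that one 10 m cell
can represent them; zero-length lines are skipped with a warning.

Rasterization assigns each cell the class covering the largest fraction
of its area, computed by exact polygon–cell intersection.  Conventions:

* Grid origin is the lower-left corner of the feature bounding box; rows
  are stored north-up; cells are half-open `[x, x+c) × [y, y+c)` with
  cell size `c` (default 10 m).
* Exact coverage ties between classes go to the lowest class code
  (deterministic; no rule is canonical here).
* With `line_priority` (default on), the best buffered-line class wins
  against the best polygon class whenever its coverage is at least as
  large.  This preserves narrow line habitats that a plain dominance rule
  would swallow wherever the underlying field polygon covers the full
  cell: a 10 m-buffered line then cuts a one-cell-wide strip.
* Cells covered by no feature carry the reserved nodata code −1 and are
  excluded from every downstream computation.

Rasterization is area-conservative up to one cell layer per class
boundary; the test suite checks `|p_vector − p_raster| ≤ perimeter·c /
area` on constructed rectangles.  A representativeness check
rank-correlates class proportions inside the union of the plot circles
with whole-map proportions (requires ≥ 3 classes, otherwise the rank
vector is degenerate).

File formats: GeoJSON FeatureCollections (property `class_code`) for
vectors; Esri ASCII grid and single-band GeoTIFF (pixel-scale/tiepoint
tags, GDAL-style nodata tag) for rasters; plain CSV for plots,
observations and result tables.

## 2. Patches and landscape metrics

Patches are maximal same-class cell sets under the eight-cell
neighbourhood rule (orthogonal + diagonal).  Patch perimeter counts every
cell side facing a different class, nodata, or the region boundary — so a
patch truncated by a moving window includes the truncation line in its
perimeter.  Region-level edge, however, follows the opposite rule by
default: the border of the analysed region is *not* edge for ED and the
class-pair edge lengths (`border_is_edge` flag), while LSI uses the total
edge including the boundary (`lsi_include_boundary` flag), matching the
raster definition of that index.  Both flags are exposed because the two
conventions coexist in practice.

The sixteen landscape-level metrics use the shared quantities: total
region area A (m²), patch areas aᵢ and perimeters pᵢ, class proportions
Pₖ, ordered cell-side adjacency counts g_kl, class-pair edge lengths
e_kl, richness m, patch count N, cell count Z.  Notable details:

* **CONTIG** uses the 3×3 template (centre 1, orthogonal 2, diagonal 1,
  template sum T = 13): a one-pixel patch scores exactly 0, large compact
  patches approach 1.
* **SHAPE** divides patch perimeter (in cell sides) by the minimum
  perimeter of any equal-area cell patch: 4k for n = k², 4k+2 for
  n ≤ k(k+1), else 4k+4.  Any square patch scores exactly 1.
* **CONNECT** counts same-class patch pairs whose minimum cell-centre
  distance is within a threshold, relative to all same-class pairs.  The
  threshold has no canonical value; the default is 100 m and it is
  recorded with the output (`connect_threshold`).  Minimum cell-centre
  distance (not centroid distance) matches the functional-joining
  reading.
* **IJI** and **PAFRAC** use natural logarithms.  PAFRAC = 2/β with β the
  OLS slope of ln aᵢ on ln pᵢ.
* Undefined cases return a `defined=False` flag instead of NaN: IJI with
  m < 3 or no edge, PAFRAC with N < 2 or constant ln pᵢ or zero slope,
  CONNECT with no same-class pair, PLADJ/COHESION on degenerate regions.

The engine computes all sixteen in one pass over shared patch and
adjacency structures (`RegionMetrics`); an independently written
brute-force implementation (BFS flood fill, explicit side enumeration,
literal formulas) lives in the test suite and must agree to 1e-9 on
random rasters.

## 3. Moving windows and plot values

A metric surface assigns to each valid focal cell the metric of the
sub-region of cells whose centres lie within the window radius
(inclusive) of the focal cell's centre — the standard centre-inclusion
discretization; on a 10 m grid a 250 m window holds 1,961 cells.  Windows
overlapping the raster edge use only interior cells, unrenormalized, per
the border rule; focal nodata cells get no value; windows where a metric
is undefined are flagged, not zeroed.

The plot value of a metric is the unweighted mean of defined surface
cells whose centres fall inside the plot circle (radius 250 m in the
motivating design).  A plots-only fast path evaluates windows only at
cells inside some plot circle; it shares the per-cell code path with the
full surface and is therefore bit-identical on those cells (tested).

## 4. Level of persistence

Observation records are presence-only rows (plot, year, visit, species);
absence is implicit and abundance columns are ignored.  For a guild of
exactly three species, each survey contributes 0–3 presences per plot;
the LOP is the sum over the survey design.  The four-year design with
visit counts (4, 5, 5, 5) gives 19 surveys and an LOP range of 0–57.
LOP is additive over disjoint survey subsets and monotone in presences
(property-tested).  A strict-coverage mode drops plots not visited at
every survey, mirroring the exclusion of incompletely covered stations.

## 5. Analytical statistics

* **Spearman screening.** Rank correlation with tie-averaged ranks;
  two-sided p from the t approximation on n−2 degrees of freedom;
  constant inputs are flagged undefined.  The three metrics with the
  largest |ρ| against the guild's LOP are selected greedily; a candidate
  whose pairwise |ρ| with an already-selected metric is ≥ 0.95 (the
  default reading of "equal to or close to 1") is skipped; |ρ| ties break
  by metric id for determinism.
* **Class derivation.** Quartiles use inclusive linear interpolation
  (numpy default, R type 7); *less preferred* is strictly below the 25%
  quartile, *preferred* strictly above the 75%, the middle half excluded.
  With 120 distinct LOPs this yields 30 cases per class.  A degenerate
  LOP distribution (q25 = q75) is an error, not a silent empty class.
* **Logistic regression.** Maximum likelihood with all three inputs
  entered in one step (statsmodels `Logit`); standard errors from the
  inverse observed information; per-coefficient Wald chi-square against
  χ²(1); classification table and percent correct at cut point 0.5.
  Quasi-complete separation (failed convergence, non-finite SEs, or
  coefficient norm above 10³) is reported as `converged=False` with
  coefficients withheld — no silent penalized fallback, because the
  reference workflow used unpenalized ML.
* **Nagelkerke R².** `[1 − exp((2/n)(ℓ₀ − ℓ₁))] / [1 − exp((2/n) ℓ₀)]`
  from the model and intercept-only log-likelihoods, clipped to [0, 1].
* **Standardized coefficients.** The fully standardized form
  β*ⱼ = bⱼ·s_{xⱼ} / √(var(η̂) + π²/3), where η̂ is the fitted linear
  predictor and π²/3 the latent logistic residual variance.  Several
  standardization variants circulate; this one is declared rather than
  asserted to match any particular historical software output.  It is
  invariant to affine input rescaling (tested by refitting under rescaled
  inputs).
* **Prediction.** The fitted equation applied cell-wise to aligned metric
  surfaces yields a P(preferred) surface and a binary suitability map at
  the cut point; cells with any undefined input stay undefined.

`GuildHabitatModel.fit()` packages the chain and returns a results object
with estimates, diagnostics, `summary()`, `predict_suitability()` and
`plot_suitability()`.

## 6. Synthetic data generator

The generator exists so that every stage is testable end to end against
known truth, with no field data.

**Landscape.** A smoothed Gaussian random field (grain scale 3 cells)
plus a coarse drift field (scale 14 cells, weight 1) is thresholded at
the empirical quantiles of the target class proportions — default 70%
arable matrix, 18% forest, 7% grassland, 5% other, emulating an
agricultural mosaic.  Two overlays add structure real rural landscapes
have and a single-field model lacks: scattered single-cell elements
(ponds, copses) at a smoothly varying density up to 10%, drawn from the
target class mix so composition is preserved in expectation, and a
Poisson number (mean 8) of straight one-cell-wide linear features with a
dedicated class.  The overlays matter statistically: they let patch
fragmentation and subdivision vary independently of composition.  Without
them all sixteen plot-level metrics collapse onto essentially one latent
gradient (pairwise |ρ| of 0.9–1.0), and no three-metric generative signal
is identifiable by rank screening even in principle.  Realized
composition tracks the targets to within ±1% on a 200×200 grid (tested).

**Surveys.** For each plot, the named metrics are computed by the moving
window, standardized across plots, and fed through a logistic link: each
guild species at each survey is present with probability
σ(b₀ + offset_s + u_plot + Σ bⱼ zⱼ), with optional per-species offsets
and an optional per-plot normal random intercept u (site quality an
ecologist did not measure).  A single root seed feeds independent
substreams for landscape, plot placement and surveys.

**Default truth.** The demonstration guild loads on CONTIG_MN (+1.2),
NP (+0.6) and PRD (−0.9) with b₀ = −0.5 — a guild tied to compact,
finely subdivided habitat with locally low habitat-type richness.  The
triple was chosen by a systematic identifiability analysis: the three
drivers sit on weakly coupled structural axes of the synthetic mosaic
(patch boundary configuration, subdivision, compositional richness), so
the selection problem they pose has a well-defined answer.  All
standardized effects exceed 0.5 in magnitude.  For the demonstration
pipeline the plot random effect defaults to sd 1.0, which keeps the
quartile-extreme classes statistically overlapping (correct rates in the
80–95% range); with sd 0 the classes become perfectly separable, which
the classifier correctly reports as non-convergence.

**What the generator does not emulate.** Species phenology and
detectability, abundance, territoriality and home-range mechanics,
spatially correlated survey effort, and real biotope-map classification
error.  Passing recovery tests therefore show that the *statistical
chain* is correct under its own assumptions, not that any particular
field system satisfies them.

## 7. Validation experiments

* **Pipeline recovery** (`recovery.recovery_experiment`): 100 independent
  campaigns on 64×64-cell mosaics (10 m cells), 200 single-cell plots
  with a 6-cell margin, 50 m windows.  Per replicate, surveys are
  simulated from the default truth, LOPs computed, and the three-metric
  screening run against all sixteen candidates; recovery means selecting
  exactly the generative triple.  Coefficients are checked by refitting
  the generative per-survey occurrence model: a plot's LOP counts
  successes in 3 species × 19 surveys = 57 Bernoulli trials, so the
  binomial logistic fit on the expanded trials is the exact maximum-
  likelihood estimator of the generative coefficients, making "unbiased
  within Monte-Carlo error" a sharp criterion.  (A single-Bernoulli
  per-plot refit at n = 200 would instead exhibit the well-known O(1/n)
  upward bias of logistic ML and conflate estimator bias with
  implementation error.)
* **Null calibration** (`recovery.null_calibration`): 2,000 null
  replicates (y independent of three standard-normal inputs, n = 60,
  matching the quartile-class sample sizes) pooled over slope
  coefficients; the Wald rejection rate at α = 0.05 must sit within
  0.05 ± 0.015.

The problem sizes above are the package defaults and keep the full suite
in the minutes range on one core.

## 8. Known limitations

* Rasterization computes exact polygon–cell intersections; it is meant
  for maps of up to ~10⁵ cells per layer, not for regional mosaics (use a
  pre-classified raster input there).
* The moving-window engine recomputes each window from scratch (with the
  structural pass shared across metrics).  This is exact and simple;
  incremental updating would be faster for full-surface runs on large
  rasters but risks drift from the per-window definition, so it was not
  adopted.
* CONNECT is quadratic in patches per class within a window; fine for
  window-sized regions, slow for whole large landscapes.
* The LOP attaches no detection model; a species present but undetected
  lowers the LOP.  Occupancy-style corrections are out of scope.
* Multinomial (more than two habitat classes) extensions and
  cross-validation of the classifier are out of scope; significance is
  reported per guild without multiple-testing correction across guilds.
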