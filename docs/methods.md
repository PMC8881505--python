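# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish.

## Study design being emulated

The pipeline reproduces a regional species-distribution study design for
forest-specialist bats: a national forest inventory samples 25-m-diameter
plots on a regular 1-km grid, recording every stem with DBH > 75 mm;
presence-only occurrence records of nine species (four tree-roosting, five
roosting in caves or buildings, two of the tree-roosters open-space
foragers) are modelled against forest-structure, forest-composition and
climate covariates with presence–background maximum entropy; per-species
training gain is then treated as the response of a second-level
trait analysis.

## Synthetic landscape generator

The generator's defaults define the study conditions used by the tests:

* **Region**: 40 × 40 km, plots on a 1-km grid (offset half a spacing),
  forest fraction 0.65. A real study region of this kind is roughly 300 km
  across; 40 km keeps a full pipeline run below ~10 s while leaving ≥ 1000
  plots.
* **Landcover mask**: a smooth random field at 100-m resolution thresholded
  at the forest-fraction quantile — forest forms patches, not salt-and-
  pepper noise.
* **Stands**: forested plots are young plantations or mature stands
  (default mature fraction 0.35, assigned from a smooth "maturity" field so
  stand types are spatially patchy at ~1/6 the region scale). Stem counts
  are Poisson (22 young / 11 mature per plot); DBH is a truncated lognormal
  above the 75-mm inclusion limit, with the fraction of large trees
  (DBH > 425 mm) controlled exactly per stand (0.004 young, 0.12 mature) by
  conditioning the lognormal on the threshold; heights follow a power-law
  allometry with lognormal noise; wood type and density come from a small
  Mediterranean species pool (pines softwood, oaks hardwood). Tree cover,
  understory cover, plantation percentage and development stage are
  plot-level fields drawn per stand type.
* **Climate**: each surface is a sum of 24 random low-frequency cosine
  waves — cheap, seedable and smooth — scaled so the marginal SD equals the
  configured amplitude. Length scales (7–11 km) are set so a 40-km region
  holds enough independent climate patches for presence–background
  contrasts; means/amplitudes are Mediterranean-like (elevation 800 ± 450 m,
  precipitation 600 ± 180 mm, Tmax 32 ± 3 °C, seasonality 550 ± 90).
* **Virtual species**: suitability is a logistic link of configured response
  terms (linear on z-scores; logistic saturating responses centred on the
  variable mean — the median of a zero-inflated variable like large-tree
  density would hand half the effect to resource-free plots; or a step
  threshold). Records pick plots proportionally to suitability and are
  jittered within 300 m (coordinate precision plus capture-site offset).
  A `sampling_noise` fraction (default 0.12) of records is drawn uniformly
  over plots, standing in for commuting/drinking/stray captures; without
  it, virtual presences can be perfectly separable from background in
  feature space, which real occurrence data never are. The default
  nine-species assemblage gives the four tree-roosters strong
  roost-availability responses (logistic on large-tree density, linear on
  DBH range and development stage; the bark-roosting analogue adds softwood
  large-tree density) and the five cave-roosters moderate climate
  responses, mirroring the empirical pattern that habitat specialists
  concentrate harder than widespread generalists.

What the generator does **not** emulate: nested-radius plot designs,
geographic range boundaries, survey-effort bias, spatially varying
detectability, temporal structure. Passing tests therefore demonstrate the
statistical machinery recovers known effects under clean sampling, not that
it would under real survey bias.

## Spatial processing

* **Un-clustering**: greedy max-neighbour elimination — repeatedly delete
  the point with the most neighbours closer than the minimum distance, ties
  broken at random under a fixed seed. The output is a subset of the input
  with all pairwise distances ≥ the minimum. The choice of algorithm is the
  largest procedural gap in the emulated design; this variant matches
  common thinning tools.
* **Interpolation**: nearest k_min–k_max plots within d_max (per mobility
  class: 2–5 within 3 km; 4–8 within 5 km; 8–16 within 7 km), quantitative
  variables averaged, categorical by mode with ties broken by the nearest
  plot's value (deterministic). Points with fewer than k_min plots in range
  are dropped, never imputed — for presences and backgrounds alike.
* **Backgrounds**: 10,000 uniform points (default), thinned at 4–5 km;
  plots closer than the exclusion distance to any presence are removed from
  the interpolation pool first. Distances are planar Euclidean on projected
  metre coordinates.
* **Forest proportion**: the binary 100-m landcover mask block-averaged by
  a factor of 25 to a 2.5-km proportion raster; partial edge blocks use the
  cells available; extraction is nearest-cell.

**Scaled demo conditions.** On a 40-km synthetic region the full-size
spatial parameters misbehave in two ways, so the bundled demo configuration
scales them: home-range distances (interpolation radius, presence
thinning) to 60%, background thinning to 25% (≈ 500 background points,
preserving the presence:background ratio), and the presence-background
exclusion buffer fixed at 0.5 km. A home-range-sized exclusion buffer in a
small region would swallow the entire mature-forest stratum from the
background pool and manufacture artificial presence/background separation;
0.5 km (half the plot spacing) keeps the buffer's actual purpose — no plot
at a presence location enters the background.

## Maximum-entropy model

The model is the Gibbs density over background points
q(x) = exp(∑ⱼ βⱼ fⱼ(x))/Z, fitted by minimising

    −(1/n) ∑_presence η(xᵢ) + log Z + ∑ⱼ λⱼ |βⱼ|.

* **Features**: linear, quadratic, hinge (both directions, knots at
  background quantiles, 50 per direction by default) and categorical
  indicators for levels observed in the background (a level absent from
  the background has no finite optimum). All features are scaled to [0, 1]
  over the background and **clamped** there — presence values outside the
  background range are not extrapolated.
* **Penalties**: λⱼ = rm × β_class(n) × sⱼ/√n with sⱼ the feature's
  presence SD (floored at 0.01) and β_class the published per-class default
  tables (hinge constant 0.5; linear, quadratic and categorical
  interpolated over the presence count). `fit` also accepts explicit λ.
* **Optimiser**: cyclic coordinate descent with soft-thresholded Newton
  steps and backtracking (objective non-increasing by construction; the
  inner loop is numba-compiled), glmnet-style active-set iteration, then a
  working-set Newton polish that puts every active feature exactly on its
  penalty bound; convergence is declared on the optimality conditions
  themselves (overshoot ≤ 1e-7 for all features, active equality within
  5e-4). The coordinate order is shuffled (seeded) over the first 40 cycles
  only, which removes path-attribution order bias while keeping the fast
  deterministic tail. A coefficient passing ±40 flags complete separation
  (a presence-supported corner with zero background mass has no finite
  optimum); the fit stops there and is marked unconverged.
* **Gain and attribution**: training gain G = mean η(presences) − log Z +
  log N_bg. Per-variable contribution is the variable's share of positive
  objective decrease along the fit path, scaled to G (non-negative, sums to
  G); permutation importance (variable permuted jointly across presence and
  background rows, gain drop with renormalised background) is the
  independent cross-check.
* **Selection and evaluation**: AICc = 2k − 2ll + 2k(k+1)/(n−k−1) with k
  the non-zero coefficient count and ll the log of raw outputs at
  presences; candidates with n ≤ k+1 are disqualified; ties go to the
  larger multiplier. Discrimination is rank-based (tie-corrected) AUC,
  cross-validated over 6 random presence folds with the full background
  reused in every fold; the reported test AUC is the fold mean.

## Null models and trait analysis

Null calibration draws presence sets of the observed size uniformly in the
region (forest-restricted drawing is available as an option) and reruns
background generation, interpolation and modelling identically; the
observed model is better than random when its test AUC exceeds the
empirical (type-7) 95th percentile of null AUCs. Replicate i is seeded
seed + i; failures are logged and skipped.

Trait tests: two-group ANOVA from raw values or from printed (mean, SD, n)
summaries — the two agree to machine precision, by construction of the
sums of squares; linear models gain ~ trait + record-count via OLS with the
trait's partial-t p reported; Holm step-down for per-variable families;
zero within-group variance is reported as an overflow flag, never a number.
Gains enter untransformed. Wing-morphology tests use within-forest foragers
only (open-space aerial hawkers excluded).

## Problem sizes used by the tests and the acceptance script

Unit tests run on tiny instances (≤ 1000 random cases per oracle test).
The study-scale checks use: the 40-km default landscape; calibration runs
of 20 replicates × 50 null datasets (n = 50 presences, 200 background,
seven quantitative covariates); and 20 assemblage runs for trait recovery.
The acceptance script reports the same quantities at 20 replicates × 30
nulls and 5 assemblage seeds. These sizes are the package's scaled study
conditions; the generator's species effect sizes are never varied between
checks.

## Known limitations

* Path attribution of gain, like any sequential credit assignment, splits
  shared gain between correlated variables; the permutation estimator is
  provided precisely because the attribution question has no unique answer.
* The empirical 95th-percentile verdict is mildly anti-conservative for
  finite null-replicate counts (the exceedance probability of the type-7
  percentile of R replicates is slightly above 5%).
* No geodesic distances, no spatially structured nulls (clustering of real
  records is not preserved), no product/threshold features, no cloglog
  output calibration, and no raster projection beyond point prediction.
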