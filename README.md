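# forestsdm

Regional-scale analysis of how forest structure and composition — as
opposed to climate alone — drive the distributions of forest-specialist
species, built around the study design used for Mediterranean forest bats:
national-forest-inventory plots, presence-only occurrence records,
presence–background maximum-entropy distribution models, null-model
calibration, and a trait-level meta-analysis across species. A synthetic
landscape and virtual-species module stands in for the raw inventory and
occurrence data, so every stage runs and is validated end-to-end without
external downloads.

It is written for quantitative ecologists who want the full chain —
from tree records to trait-level inference — as importable, tested code.

## The analysis

1. **Forest variables.** Inventory plots (25 m diameter, 1-km grid, every
   stem above 75 mm DBH) are summarised into per-plot structure and
   composition: stem densities per hectare, density of large trees
   (DBH > 425 mm), basal area ∑π(DBH/2)², basal-area-weighted wood density,
   size ranges, species richness and the dominant species. Climate surfaces
   are extracted at plot locations. Variables are screened by
   single-variable model gain and greedy removal at |r| ≥ 0.70.
2. **Home-range-scaled interpolation.** Occurrence records are un-clustered
   (greedy max-neighbour thinning at 0.5–2 km), then each record is
   characterised by the mean (mode for categoricals) of its nearest
   k_min–k_max plots within a species-mobility-dependent radius. Background
   points are drawn uniformly, thinned at 4–5 km, and interpolated from a
   plot pool that excludes plots near presences.
3. **Maximum entropy model.** A Gibbs density over the background,
   q(x) = exp(∑βⱼfⱼ(x))/Z, with linear/quadratic/hinge/categorical features
   scaled to [0,1] on the background, fitted by minimising the L1-penalised
   negative mean presence log-density with coordinate descent plus an
   active-set Newton polish. At the optimum the defining property holds:
   |E_presence[fⱼ] − E_model[fⱼ]| ≤ λⱼ, with equality for active features.
   Feature classes and the regularization multiplier are tuned by AICc;
   discrimination is the 6-fold cross-validated AUC. Training gain
   G = mean log q(presences) + log N_background is decomposed into
   per-variable contributions by path attribution (permutation importance
   is available as an independent estimator).
4. **Null models.** Each species' test AUC is compared against the 95th
   percentile of AUCs from random presence sets pushed through the
   identical downstream procedure.
5. **Trait meta-analysis.** Per-species gains (total, per mechanistic
   variable group, per variable) are related to roosting ecology, wing
   loading and aspect ratio with two-group ANOVAs (raw or recomputed from
   printed mean/SD/n summaries) and linear models with the record count as
   a covariate; per-variable families are Holm-corrected.

## Worked example

```bash
python analysis/01_simulate_landscape.py --seed 1
python analysis/03_fit_species_models.py --seed 1
python analysis/05_trait_analysis.py    --seed 1
```

The first call prints

```
landscape: 1023 forested plots on the grid (358 mature stands), 18447 trees
fraction of trees above the 425-mm large-tree threshold: 0.029
```

— a 40-km landscape whose inventory respects the 75-mm inclusion rule, with
large trees concentrated in the scarce mature stands. The model stage then
reports, per virtual species (four tree-roosting driven by roost
availability, five climate-limited), the records used after un-clustering,
training gain and cross-validated AUC:

```
species  n_records  n_background  training_gain  auc_test_mean
   Vbar        114           500          0.864          0.706
   Vbec        116           500          0.778          0.736
   Vlas         89           500          0.659          0.708
   ...
   Veur        128           500          0.315          0.597
```

Tree-roosters carry systematically higher gain than the climate-limited
cave-roosters, and `05_trait_analysis.py` formalises that contrast:

```
summed forest-variable gain by roosting ecology:
  tree-roosting (4 sp): mean 0.528
  non-tree      (5 sp): mean 0.177
                        test        F  df1  df2     R2      p
anova forest_gain ~ roosting  26.9187    1    7 0.7936 0.0013
```

The F with (1, 7) degrees of freedom is the two-group ANOVA of summed
forest-variable gain between roosting guilds; at this seed roosting ecology
explains 79% of the between-species variance in forest dependence — the
virtual assemblage's known trait effect, recovered end-to-end.

`analysis/04_null_models.py` calibrates the better-than-random verdict
(≈5% firing rate on no-signal species, ~100% on a strongly forest-driven
one). The same stages are scriptable through the `forestsdm` CLI
(`simulate`, `variables`, `interpolate`, `fit`, `nulls`, `traits`, `all`)
with a YAML config.

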