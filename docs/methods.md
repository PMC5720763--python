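# Methods

## The delta log-normal model

Fisheries survey abundance (CPUE) is typically zero-inflated and
right-skewed: most hauls catch nothing, a few catch a lot. A single
distribution fits such data poorly, so the response is decomposed into
a hurdle pair. Occurrence is the indicator `1[y > 0]`, modelled by a
bernoulli gradient-boosted tree ensemble; magnitude is `ln(y)` on the
positive subset, modelled by a gaussian (squared-error) ensemble. Both
components see the same explanatory variables; the model assumes the
covariates drive occurrence and magnitude through separate, possibly
different, nonlinear functions, and that positive catches are
log-normal around the fitted log-mean.

Back-transforming a log-scale prediction with `exp()` alone estimates
the conditional *median*, not the mean. Duan's smearing estimator
corrects this nonparametrically: `S = (1/n) Σ exp(r_i)` over the
training residuals `r_i` of the log-scale fit. For exactly normal
residuals `S → exp(σ²/2)`; the estimator needs no normality assumption.
The combined per-cell index is `p · S · exp(ĝ)`, which equals the
model's expected abundance under the hurdle factorization. When the
response is not zero-inflated, the hurdle is skipped and one ensemble
(gaussian or poisson) is fitted directly; occurrence probability is
then reported as 1 so the combined index is just the prediction
(clipped at 0, the response being an abundance index).

Zero inflation is auto-detected as a proportion of exact zeros ≥ 0.5
(threshold configurable). Proportion-of-zeros was chosen over
median-based rules because it is the quantity the hurdle split actually
consumes.

## Fitting, stopping, and selection

Ensemble fitting delegates to scikit-learn gradient boosting.
Tree complexity `tc` maps to `max_leaf_nodes = tc + 1`, i.e. `tc`
splits per tree, matching the interaction-depth semantics the fisheries
BRT literature uses; `lr` is the shrinkage; the bag fraction `bf` is
the per-iteration training subsample. The poisson family uses the
histogram-based booster (the only installed implementation of Poisson
loss), which has no subsampling, so `bf` is ignored there with a
warning.

The tree count is not a free parameter: trees grow in blocks of 50,
and after each block the mean held-out deviance over k CV folds is
recorded (bernoulli: −2·mean log-likelihood; gaussian: MSE; poisson:
mean unit deviance). Growth stops after 2 consecutive blocks without
improvement, or at 10,000 trees. The selected size is the argmin of
the CV curve, and the final ensemble is refitted at that size on all
rows. A minimum at the very first block triggers a "learning rate may
be too high" warning rather than an error.

The hyperparameter search nests `bf` within `lr` within `tc`, fits
every combination, and selects by minimal mean CV deviance; ties break
by fewer trees, then lower `tc`, then lower `lr`, then lower `bf`,
making selection deterministic and invariant to candidate ordering.
CV deviance was preferred over training AUC/correlation as the
selection criterion because it is comparable across all three families;
the alternatives are retained in the model report.

Simplification is backward elimination: repeatedly drop the variable
whose removal least increases CV deviance, accepting a removal while
the increase stays within one fold-SE of the current model (the 1-SE
rule). The trail of dropped variables and deviance deltas is reported.

Fold assignment is stratified on the binary response for the bernoulli
component and derived from the run seed, so the whole fit→predict
pipeline is bit-reproducible from one integer. Missing explanatory
values are median-imputed at fit time (logged); grid cells with missing
explanatory values get missing predictions, never zeros.

## Diagnostics

Relative influence is the ensemble's impurity-based attribution of
loss reduction, normalized to 100 per component (partial-dependence
variance for the histogram booster, which exposes no impurity
attribution). Partial dependence clamps one variable to a 100-point
grid over its sampled range and averages link-scale predictions over
the training rows; dot plots show each row's full-model prediction
minus the component mean against the variable's observed value.
Two-way interaction strength is the variance of the 20×20 joint
partial-dependence surface after removing additive row/column effects
(zero for an exactly additive pair); the pair order is canonicalized so
the statistic is exactly symmetric. All diagnostics are computed on the
link scale — the exponentiated gaussian curve scaled by the smearing
factor is monotone-equivalent, so rankings are unaffected.

## Representativeness (RSB)

For each explanatory variable, the grid's values define 10 equal-width
bins (the grid is the prediction universe; sample values outside its
range clamp to the end bins). A cell's score for that variable is
|sample relative frequency − grid relative frequency| of the bin
containing the cell's value; the total is the sum over variables, so
each variable contributes at most 1. A survey that mirrors the grid's
bin proportions scores exactly 0 everywhere. Scores are unsigned by
default; a signed variant (positive = undersampled) aids map reading.
The bin count is the main tuning knob: fewer bins forgive coarser
coverage.

## Conservation surfaces and the decision-support tool

Multiple species' combined indices are each scaled to unit maximum
(unit-sum optional) and summed with user weights; this prevents an
abundant subset from obfuscating a rare one, since both contribute
exactly 1 at their own hotspots.

The MPA tool takes per-cell species abundances ("good"), a stressor
surface to avoid displacing ("bad", typically fishing effort), and
optionally a conservation surface. The per-species biomass target is
`Bpa = (1 − HRMSY) · total predicted biomass`: HRMSY is the
harvestable fraction at MSY, so the complement is the escapement that
must stay protected. The formula is injectable (`bpa_rule`) because
management bodies may supply an external tonnage instead. Cells are
ranked by one of four schemes — combination (descending mean of
unit-scaled abundance and reversed unit-scaled effort, endpoints 0 =
max effort/no fish, 1 = no effort/max fish; the arithmetic mean is the
default aggregator, geometric optional), biomass (descending
abundance), effort (ascending effort, ties toward high abundance so
zero-effort hotspots go first), conservation (descending conservation
value) — with residual ties broken by cell index. The closure is the
minimal ranking prefix whose cumulative abundance reaches the target.
Closures cascade in at-risk order: each later species is first
credited with its biomass inside earlier closures, then topped up from
its own ranking. Closures are cell sets; contiguity is not enforced.

A caveat established by this package's own experiments: the
effort-sort closure does **not** always overlap less effort than the
combination sort. Because effort sort ignores abundance it needs more
cells to reach the same target, and the summed effort of the larger
closure can exceed the combination sort's — on random independent
lognormal toys it usually does. The orderings are exactly as specified
(verified cell-by-cell against a brute-force oracle); the inequality
holds when closure sizes coincide, e.g. under near-constant per-cell
abundance, which is the regime the intuition comes from.

## Run-to-run variability

Bagging makes runs stochastic. `run_loops` repeats the identical run
with seeds `base_seed + k`, then reports per-cell mean, sd (n−1
denominator) and CV = sd/mean (missing where the mean is 0; exactly 0
where runs are byte-identical), per-variable influence
min/mean/max/variance, and pointwise partial-dependence envelopes on a
common x-grid. Simplification defaults off inside loops so the
variable set is constant across runs; with it on, absent variables
count as influence 0.

## Synthetic data

The generator emulates the structure, not the values, of trawl-survey
data. Each explanatory field on the lattice is a random planar trend
plus Gaussian-smoothed white noise (smoothing σ = 4 cells),
standardized; successive fields are orthogonalized against earlier
ones so the designated noise covariates are genuinely uninformative
rather than collinear proxies of the signal (random planar trends in a
2-D domain would otherwise correlate strongly). The default truth has
4 covariates, 2 active in both hurdle components (occurrence
coefficients 1.0/−0.8, intercept −0.5, giving ~50–60% zeros;
log-abundance coefficients 0.7/−0.5, intercept 1.0) and log-scale sd
0.7 for the long right tail. True expected abundance is available in
closed form, `logistic(η_occ) · exp(η_abn + σ²/2)`, enabling
parameter-recovery tests. Stations are placed uniformly without
replacement; a biased option (weights ∝ exp(strength·covariate))
exists to make representativeness scores non-trivial. Effort surfaces
are exponentiated Gaussian-copula mixtures hitting a target Spearman
correlation with true abundance.

What the generator does not emulate: spatial autocorrelation of the
*residuals* (stations are conditionally independent), preferential
sampling feedback, measurement error in covariates, and temporal
structure. Passing recovery tests therefore show the estimator chain
is correct, not that real surveys are this easy.

## Numerical and output conventions

Problem sizes used by the test suite and acceptance script — 40×40
grids with 1000 stations for recovery, 20×20/300 for shared fixtures,
100 random DST toys of ≤200 cells — were chosen as the smallest sizes
at which the checked signals are comfortably identifiable.
Probabilities are clipped to [1e-12, 1−1e-12] inside the bernoulli
deviance; bag-fraction feasibility uses integer arithmetic
(`(k·n)//100`) so `floor(bf·n)` is exact on the 0.01 grid; cell-size
inference takes the modal gap between sorted unique centroids with
ties broken toward the smaller gap; rasters are north-up with centroid
registration and a 1e-6° alignment tolerance. Maps are PNG in colour
and greyscale with missing cells drawn distinctly from low values;
rasters export as ESRI ASCII grid (plain text); coastline polygons are
read from GeoJSON or WKT and clipped by rectangle intersection —
acquisition of coastline data is out of scope, keeping builds offline.
CSVs are written with `%.10g` floats so identical runs are
byte-identical. Model files carry a schema version and refuse to load
mismatched versions.
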