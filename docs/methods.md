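# Methods

## The model

Habitat suitability is modelled as a Bernoulli probability
p(x) = logistic(F(x)) with an additive tree ensemble on the logit scale,
F(x) = β₀ + Σₜ fₜ(x). The intercept β₀ is the logit of the training
prevalence. Each stage fits one shallow regression tree to the current
gradient residuals y − p on a fresh bag of training rows, takes a single
Newton step per terminal node, shrinks the tree by the learning rate and
adds it to the ensemble. This is classical stagewise gradient boosting
of the Bernoulli deviance; the package implements it from scratch
because the stagewise cross-validated selection of the tree count is the
methodological core being exercised, not a detail to delegate.

Assumptions worth stating: records are conditionally independent given
the predictors (spatial thinning is the pipeline's only concession to
spatial autocorrelation of sampling); pseudo-absences are an adequate
contrast sample for the available environment, not true absences, so
p(x) is a relative suitability index rather than an occupancy
probability; predictors are co-registered and complete (records on
nodata cells are dropped upstream — trees never see missing values).

## Tunable parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `bf` | bag fraction per tree (without replacement) | 0.5 | standard stochastic-boosting value; grid explores 0.1–0.75 |
| `lr` | shrinkage per tree | 0.01 | small enough that nt is selected well inside the cap at calibration sizes |
| `tc` | splits per tree (interaction depth) | 2 | pairwise interactions; grid explores 1–4 |
| `ss` | trees per stagewise block between CV evaluations | 25 | profile resolution vs. cost |
| `n_folds` | folds of the stagewise CV | 10 | conventional |
| `patience` | CV evaluations without improvement before stopping | 2 | the profile is smooth at these sizes; 2 blocks suffice |
| `min_obs_per_node` | smallest terminal node | 10 | guards Newton steps on tiny nodes |
| correlation cutoff | cluster cut on Pearson r | 0.5 | groups predictors sharing ≥ half their variation in common |
| VIF ceiling | collinearity screen | 5 | conventional evidence-of-collinearity bound |
| pseudo-absences | background sample size | 2,000 | conventional calibration size at the target resolution |
| train fraction | stratified share per class to training | 0.30 | the calibration/evaluation split this pipeline standardizes on (the larger 70% share is held out for evaluation and thresholding) |
| km→degree constant | for geographic target distances | 1/111.32°/km | ~1 km cells at the latitudes of interest |

`tc` is deliberately defined as the number of splits (so `tc` = 1 is a
stump); counting "nodes" is ambiguous between internal and terminal
nodes, and only splits make 1–4 a meaningful range.

## The synthetic generator

`make_env_grid` smooths white noise with a Gaussian kernel (sigma =
autocorrelation range in cells) and standardizes, then builds each
block's layers as √r·shared + √(1−r)·own from independent fields, so
within-block correlation converges to the target r and between-block
correlation to zero — giving the correlation-clustering step an
unambiguous truth at the 0.5 cutoff. The suitability truth is a logistic
of summed sigmoid ramps: flat below a threshold, rising steeply through
it, saturating — the response shape climate-limited species typically
show. The default study makes the species require *both* a warm-enough
temperature driver and a wet-enough precipitation driver (each ramp
alone leaves the logit deep below zero), which yields roughly a fifth of
the landscape suitable and a Bayes AUC near 0.87 — the discrimination
level a well-calibrated regional SDM reaches. Presences are drawn with
replacement proportionally to suitability (repeat visits, as in
aggregated databases; cleaning dedups, thinning enforces one per cell).
Futures are built by additive deltas, optionally spatially varying, so
downstream attribution has an exactly known answer.

What the generator does **not** emulate: real bioclim derivations and
their heavy-tailed distributions, anisotropic or long-range spatial
structure, observer bias correlated with environment (a bias layer can
be supplied but none is default), coastline/boundary geometry, and
dispersal limits. Passing tests therefore demonstrate that the machinery
recovers a known signal under clean conditions — not that any real
species' range is predicted correctly.

## Numerical choices

- Probabilities are clipped to [1e-12, 1 − 1e-12] inside the deviance.
- Terminal Newton steps guard the denominator at 1e-8 and cap raw leaf
  values at ±4, bounding any overshoot of the one-step update (with
  shrinkage this also keeps full-bag training deviance monotone).
- Split candidates are midpoints between consecutive distinct sorted
  values; gains are squared-error reductions of the working response;
  within a tree, growth is best-first. Ties effectively resolve to the
  lowest feature index / first midpoint encountered.
- CV-deviance profile: evaluated at multiples of `ss`; selected nt is
  the argmin, ties to the smaller nt; hitting `max_trees` while still
  improving is flagged in model metadata rather than raised.
- maxSSS: candidate thresholds are midpoints between consecutive unique
  scores plus below-min/above-max sentinels; presence is predicted at
  score ≥ threshold; sums within 1e-12 of the maximum are treated as
  tied and the smallest threshold wins (last-ulp float noise must not
  decide a threshold). All-equal scores are flagged degenerate.
- Quartiles use linear interpolation between order statistics; box-plot
  whiskers are the most extreme values within 1.5·IQR of the hinges.
- Stratified splits send round(f·n_c) records of each class to training,
  round half up.
- Model JSON stores floats via Python's shortest-repr round-trip, so
  serialize → deserialize is prediction-exact.

## Design choices

- **Stagewise CV, not nested refits.** The fold models used to select nt
  grow in parallel with the full model; their pooled held-out
  predictions at the selected nt are the cross-validated AUC/deviance
  reported for a candidate. This is the standard stagewise procedure and
  avoids multiplying cost by the fold count for no methodological gain.
- **Thinning is one-record-per-grid-cell**, applied to each label class
  independently on the same grid; where a cell holds both classes the
  presence wins. A pairwise minimum-distance thinning is deliberately
  not provided. By default pseudo-absences are generated after thinning,
  within the raster's valid mask, so they never share a cell with a
  retained presence.
- **Clustering distance is 1 − |r|** (sign-free redundancy), complete
  linkage by default so no merged pair exceeds the cut height;
  average/single linkage are configurable.
- **Point-biserial, not latent-normal biserial**: the label correlate is
  the Pearson correlation with the 0/1 coding, computed in the classical
  (M₁ − M₀)/s_x · √(pq) form.
- **VIF removal is iterative worst-first** with an explicit
  least-squares solve; perfect collinearity reports VIF = ∞ instead of
  raising.
- **Selection rule is total**: AUC desc, deviance explained desc, lr
  asc, then tc/bf/ss/distance asc — the documented tie-break chain makes
  grid selection reproducible.
- **Change maps compare binary ranges**: the present *binary* map (not
  the continuous suitability) is compared with the future GCM composite;
  future presence defaults to strict all-GCM agreement (composite = 2
  for two GCMs), with `consensus="any"` exposed. Change percentages are
  cell-count shares of the present binary range.
- **Rasters travel as plain-text ASCII grids.** The six-line-header
  format is fully expressive for single-band co-registered layers, is
  diffable and dependency-free; the reader/writer round-trips exactly.
- The geographic validity rules (|lat| ≤ 90, |lon| ≤ 180) apply only
  when coordinates are declared geographic; projected map units skip
  them.

## Problem sizes of the worked runs

The bundled study uses a 200×200 landscape (8 layers in 3 blocks), 800
presence draws thinned at one cell, 2,000 pseudo-absences, BRT fits at
bf 0.75 / lr 0.05 / tc 3 / ss 25 with 5 stagewise folds and a 500-tree
cap; the change scenario runs at 100×100 with 1,000 pseudo-absences.
These sizes give stable recovery (selection returns one variable per
block; the two truth drivers take ~95% of influence; CV AUC sits within
a few hundredths of the Bayes AUC) while a full run of the acceptance
script completes in seconds.

## Known limitations

- No reprojection: all inputs must already be co-registered.
- No missing-value handling inside trees; records on nodata cells are
  dropped (and counted) at feature extraction.
- Bernoulli loss only; no Poisson/multinomial responses, monotonicity
  constraints or interaction-strength statistics.
- Pseudo-absence contrast means outputs are relative suitability;
  thresholded maps inherit the arbitrariness any binarization has, even
  with maxSSS.
- No dispersal constraints, land-use masking or extrapolation (MESS)
  diagnostics in the projection step.
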