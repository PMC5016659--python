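# Methods

## The risk model

Collision risk on road segment *i* is treated as the rate of a Poisson
encounter process whose intensity is multiplicative in exposure and hazard:
`C_i = exp(β0 + β1 ln O_i + β2 ln V_i + β3 ln S_i)`, with `O_i ∈ (0, 1]`
the relative likelihood of species occurrence, `V_i > 0` the daily traffic
volume (AADT, vehicles/day) and `S_i > 0` the traffic speed (km/h). The
observable is binary — did the segment record at least one collision in
the study window — with `p_i = 1 − exp(−C_i)`. Because
`ln(−ln(1 − p_i))` is linear in the log predictors, a binomial GLM with
the complementary log-log link estimates (β0…β3) directly; the logit link
would not have this rate interpretation. Under exact proportionality of
risk to `O·V·S`, β1 = β2 = β3 = 1 and `a = e^β0` is the constant of
proportionality.

Assumptions: collisions are independent across segments given (O, V, S);
the window is implicit in β0 (doubling the observation window shifts β0 by
ln 2, nothing else); occurrence, volume and speed are static over the
window; multiple collisions on one segment carry no extra information
(binary coding).

### Fitting and evaluation

The GLM is fitted by IRLS (statsmodels, tolerance 1e-8, max 100
iterations); non-convergence or coefficients diverging past 1e4 raise an
error naming possible separation. Predictors are **not** standardised, so
coefficient magnitudes are interpretable on the raw ln scale; β0 absorbs
any unit rescaling of V or S. O is floored at 1e-6 before logging.
Deviance explained is `100 × (null − residual)/null`. The per-term ANOVA
is *sequential*: terms are added in a stated order (default
ln O, ln V, ln S — exposure first) and each share is that term's deviance
drop over the total; shares sum to one but are order-dependent, which is
why the order is an explicit argument. The flat "alternative" model swaps
the three structured predictors for the raw covariates (one linear term
each) on the same records, making AIC/deviance/ROC comparisons paired.
Hold-out validation uses an independently simulated collision draw on the
same network (the synthetic analogue of a later reporting year), scored by
ROC AUC and a decile calibration table.

## Submodels

**Occurrence** (exposure): stochastic gradient-boosted classification
trees on presence vs. uniform background points. Defaults follow BRT
practice for distribution modelling: tree complexity (terminal-node limit)
5, learning rate 0.005, bag fraction 0.5. The ensemble size is the stage
minimising mean k-fold cross-validated binomial deviance (default 10
folds; the pipeline uses 5 on small scenes), searched up to a `max_trees`
cap of 1000 by default — synthetic scenes select their optimum well below
real-data tree counts. Covariates are screened beforehand so all pairwise
|Pearson r| < 0.75; of an offending pair the variable with the larger mean
absolute correlation to the others is dropped (ties to column order,
constant columns dropped first with a warning). Reported metrics:
training-data deviance explained (mean binomial deviance), held-out-fold
CV AUC (mean ± sd), per-variable contributions (impurity importances
rescaled to 100%), and partial-dependence curves. Predictions over the
raster stack are clamped to [1e-6, 1−1e-9] so downstream logs are safe.

**Traffic** (hazard): random forests with 500 trees, other
hyperparameters at library defaults. Volume is fitted on ln(AADT) — AADT
is approximately log-normal — and predictions are exponentiated back
without bias correction (a smearing correction was considered and left
out: the plain back-transform is what the coefficient interpretation
expects, and the forest's OOB error already reflects the log scale).
Volume predictors (KMTODEV, KMTOHWY, POPDENS, RDCLASS, RDDENS) are
screened at |r| < 0.7; speed uses exactly RDCLASS and RDDENS. Road class
enters as an ordered integer 6 (freeway) … 1 (local), a proximal measure
of design intensity. Percent variance explained is out-of-bag:
`100 × (1 − MSE_oob / var(y))`.

## Geoprocessing

The analysis grid is square (default 1 km cells), half-open
`[x, x+w) × [y, y+h)` with a closed outer boundary, so every point has
exactly one cell. Roads are split at cell boundaries by exact parametric
intersection of each polyline edge with the grid lines; contiguous
within-cell runs become segments, total length is conserved to machine
precision, and clipped slivers under 1 mm are merged into a neighbouring
segment. Segment midpoints (at half arc-length) sample the occurrence
raster by nearest cell, no interpolation. Collision reports are screened
by positional accuracy (≤ 300 m kept; the boundary value is retained and
the threshold is configurable), snapped to the segment minimising
point-to-polyline distance (ties to the lowest segment id), and collapsed
to a binary code per segment. Background segments are a uniform draw
without replacement from the non-collision-coded segments, twice the
number of collision segments by default. All geometry is planar in one
projected CRS; no geodesics.

## The synthetic scene generator

The generator emulates the statistical structure of the source datasets,
not any geography. All randomness flows from one seed through named
substreams, so a scene is a pure function of (config, truth, seed) and
changing e.g. the road count does not perturb the rasters.

- **Covariates**: Gaussian white noise per layer, smoothed with a Gaussian
  kernel (default scale 5 cells) and re-standardised — a controllable
  stand-in for spatially autocorrelated environmental rasters.
- **Roads**: gently meandering random walks (8 steps, heading jitter
  sd 0.15 rad), class drawn from a configurable six-class mix, length
  scaled by class (freeways ≈ 0.9 of the scene diagonal down to locals
  ≈ 0.15), clamped to the extent.
- **Species points**: background uniform; presences rejection-sampled with
  acceptance probability `logistic(occ_intercept + occ_coefs · x)`. The
  default generator is spatially unbiased; an optional road-proximity
  weight `exp(−d_road/decay)` is available to emulate survey records
  clustered near roads, off by default.
- **Traffic truth**: `ln AADT = 5.3 + 0.55·RDCLASS − 0.06·KMTODEV −
  0.03·KMTOHWY + 4e-4·POPDENS + 0.05·RDDENS + N(0, 0.45)`, making road
  class the dominant driver; speeds are class means (102 … 51 km/h) minus
  1.5·RDDENS plus N(0, 3), rounded to the nearest 10 and clipped to
  [40, 110] like posted limits. Counts and limits are observed on a 30%
  segment subset, roughly the situation where counters cover major roads
  only.
- **Collisions**: `Y_i ~ Bernoulli(1 − exp(−C_i))` from the rate model
  with known β. Each collision-coded segment also yields a *report*: a
  point jittered isotropically (sd 50 m) with a gamma(2, 75)-distributed
  accuracy attribute (mean 150 m), so a realistic share of reports fails
  the 300 m screen and the record→filter→snap→code path is exercised, not
  bypassed.

Default study conditions: 900 presences and 10,000 background points
(matching the convention of 10,000 random background samples), a 40 × 40 km
scene at 1 km resolution, 120 roads; tests and the acceptance script use
30 km scenes with 500 presences / 2,000 background points so the full
suite runs in under a minute — sizes chosen as the smallest at which the
submodels are stably estimable, and stated here as the package's own
problem sizes. The "strong-signal" condition used for truth-recovery
checks sets |occ coefficients| between 1 and 2.2 with intercept −3: a
*rare* species is deliberate, because presence/background AUC is bounded
by the occupied-area fraction, and a generalist occupying 40% of the scene
caps AUC near 0.8 regardless of model quality.

## What passing tests do and do not show

The generator's occurrence truth is logistic-*linear* in the covariates.
Real occurrence surfaces are not, and this matters for one comparison:
the flat "alternative" GLM (raw covariates, one linear term each) can
represent `β1 ln O` almost exactly in this synthetic world (for a rare
species `ln O ≈` the linear predictor), while the structured model
carries submodel prediction error. Across replicate scenes the flat model
therefore explains on average ~4 points more deviance than the structured
model (range −3 to +11 at a few hundred training segments), a larger and
noisier gap than reported on real data. The synthetic comparison shows the
two models are of broadly similar quality; it cannot show the real-data
result that the structured decomposition costs almost nothing in fit.
Similarly, synthetic hold-out AUCs (0.79–0.93 by seed) sit above the
real-data range because the generating process is exactly the fitted
model's family. Parameter recovery, calibration, coverage and geometry
results transfer directly; absolute fit metrics do not.

Other limitations: no survey bias in the default species sampler (real
atlas records cluster near roads and towns); no temporal or diel
structure; collision reports are one per collision-coded segment; no
spatial autocorrelation in the GLM residuals (real binary maps have it,
biasing standard errors — coverage results apply to independent
outcomes); road networks are non-intersecting walks, not connected graphs.

## Numerical choices

- cloglog via `log(-log1p(-p))` and its inverse via `-expm1(-exp(η))`;
  roundtrip exact to < 1e-10 over p ∈ [1e-9, 1−1e-9]. Precision in η-space
  necessarily degrades as p → 1.
- Occurrence probability floor 1e-6 before logging; BRT raster predictions
  clamped to [1e-6, 1−1e-9].
- IRLS tolerance 1e-8, max 100 iterations; separation flagged when
  |coefficient| exceeds 1e4.
- Sliver tolerance 1e-3 m in road splitting; boundary points resolved by
  the half-open cell convention.
- Tie-breaks: nearest-segment ties to the lowest segment id;
  correlation-prune ties to the earlier column.
- Staged BRT probabilities are accumulated in float32 for memory and
  promoted to float64 before deviance computation (float32 cannot
  represent 1 − 1e-12).
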