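# Methods

`oceanssf` analyses how migrating birds choose routes across ocean
barriers, combining a geographic optimum (the least-cost path through an
island chain) with a statistical model of realized choices (a step
selection function fitted by conditional logistic regression).  This
note records the models, the numerical choices, and what the synthetic
test system does and does not establish.

## The step-selection model

Telemetry fixes, thinned so consecutive fixes are at least one hour
apart, define *observed steps* (great-circle segments between
consecutive fixes).  Each observed step is matched with M alternative
steps sharing its start point and start time; alternative lengths and
turning angles are drawn independently, with replacement, from the
pooled empirical distributions of the observed steps (no binning or
kernel smoothing — the raw frequency distribution).  The first step of a
track, which has no previous heading, uses its own heading as the
reference direction for its alternatives.

Each step is annotated at its **end point** (configurable to start or
midpoint) by bilinear interpolation in the covariate rasters.  The wind
layer is the one nearest in time to the stratum's start; wind layers are
coarse (6-hourly here) and no temporal interpolation is attempted.  The
wind vector (u eastward, v northward) is decomposed along the step
heading θ (clockwise from north):

    wind_support = u sin θ + v cos θ        (signed; < 0 is headwind)
    crosswind    = |u cos θ − v sin θ|

The decomposition is a rotation, so support² + signed-crosswind² equals
wind speed² exactly.  Crosswind enters the model as a magnitude: a
side-wind penalty should not depend on which side the wind comes from,
and a signed covariate would average left and right drift to zero.  The
signed value is kept as a column (and a config switch) for users who
want drift direction.

With one observed (case) step and M alternatives per stratum, the
conditional likelihood is the stratum-wise softmax

    ℓ(β) = Σ_strata [ βᵀx_case − log Σ_j exp(βᵀx_j) ],

maximized by Newton–Raphson from β = 0 with step-halving,
log-sum-exp–stabilized, analytic gradient and Hessian.  Convergence:
max |gradient| < 1e-8 or relative ℓ change < 1e-12.  Standard errors
come from the inverse observed information; p-values from the normal
(Wald) approximation.  Separation is detected (non-convergence with
diverging coefficients) and reported, never penalized away — at a few
dozen strata users must see it.

Covariates are z-scored on the pooled case+control sample (SD with
n−1).  Interaction terms are products of the scaled main effects, as an
R-style `scale()` + `a:b` workflow would produce; products are not
re-scaled.  A scaling table (mean, SD per variable) is returned for
back-transformation and can be supplied externally, e.g. to apply
training-fold moments to a held-out fold or a simulation's declared
truth scale.

Model selection is backward stepwise: from the full model (main effects
plus the distance×wind-support and distance×crosswind products), the
single droppable term with the largest Wald p among those with p > 0.05
is removed per stage — a main effect is never dropped while a product
containing it remains — and every fitted model's coefficients and AIC
are recorded.  The minimum adequate model is the lowest-AIC fit over the
whole trace, ties broken toward fewer terms.

## Validation

**Case-control k-fold cross-validation** (defaults k = 5, 10 rank bins,
100 repetitions): strata are shuffled into k folds; the model refitted
on k−1 folds scores every step of the held-out strata; the case's score
rank within its stratum (rank 1 = highest, average ranks on ties) is
pooled over folds and mapped to bins through the centered quantile
(rank − ½)/size.  The mapping matters: a plain ceil(rank/size·n_bins)
parks the surplus rank in the *last* bin whenever n_bins does not divide
the stratum size, which biases even a chance tally to ≈ −0.3; the
centered map parks it centrally, where it only adds a small symmetric
bump.  The adherence score is the Spearman correlation of bin index with
case frequency, negated so that good models score positive; if every
case lands in a single extreme bin (no rank-order information left for
Spearman) the score is ±1 by convention.  A chance baseline repeats the
tally with one uniformly drawn alternative per stratum.  One score per
repetition, pooled across folds (stabler bin counts at a few dozen
strata than per-fold scores).

A property of this scheme worth knowing: under a null model the
per-dataset adherence is frozen noise — a correlation over 10 bin
counts, whose dispersion (SD ≈ 1/3) does not shrink with the number of
strata, and which repetitions of the same dataset do not average away.
Unbiasedness (mean adherence 0 for observed and chance alike) is
therefore a statement about expectations over independent datasets, and
that is what the tests and the acceptance script verify.

**Permutation importance** (default 10 permutations): each term's column
is shuffled across all rows — breaking its link to strata and outcomes;
interactions are recomputed from the shuffled factor — and ℓ is
re-evaluated at the fitted β without refitting.  The raw importance is
the mean log-likelihood drop; sum-normalized shares are reported
alongside, since normalization conventions differ between studies.

## Least-cost path

The conductance surface is 1/(d + ε) where d is great-circle distance
(km) from each cell center to the nearest coastal cell center (a land
cell with a sea 4-neighbour or vice versa; exact nearest-neighbour via a
k-d tree on the unit-sphere embedding).  ε defaults to one cell diagonal
in km: the inverse layer is undefined at d = 0, and a cell-scale floor
keeps coastal conductance finite and resolution-consistent.  The grid
becomes an 8-connected graph (4 or 16 configurable); the edge between
neighbouring cells costs great-circle length divided by the arithmetic
mean of their conductances, matching the transition/geo-correction
construction conventional in raster connectivity tooling, and Dijkstra's
algorithm extracts the optimum.  Start/end are user-supplied coordinates
(typically the last mainland fix and the first destination fix), snapped
to cell centers.

## The synthetic study system

The generator (`SimConfig` defaults) emulates an autumn over-water
raptor migration at the data scale of a small telemetry study:

- **Geography**: a 34°-tall, 22°-wide grid at 0.25° resolution holding a
  300 km-radius landmass at the northern edge, another at the southern
  edge, and 8 disc islands (radius 30 km) jittered along the connecting
  arc.  The box leaves generous sea room so a simulated track cannot
  reach the boundary.
- **Wind**: prevailing (u, v) = (−2, −5) m/s — a wind toward the
  south-southwest supporting southbound flight — plus spatially smoothed
  noise (SD 2 m/s, 5-cell moving-average correlation length), refreshed
  every 6 h.  Boundary-layer height, cloud and humidity are generated as
  smooth fields with **no** selection effect, to exercise model
  selection.
- **Movement kernel**: gamma step lengths (shape 5, scale 8 km; mean
  40 km per hourly step) and wrapped-normal turning angles
  (concentration 4 ⇒ SD ≈ 29°) — plausible for a mid-sized soaring
  migrant but free choices, not species claims.
- **Selection**: at each move, 101 candidate endpoints are drawn from
  the kernel and one is chosen with probability softmax(β_trueᵀx), where
  x = scaled (distance to coast, wind support, crosswind, distance ×
  wind-support) and β_true = (−1.36, 1.15, −0.41, 0.29).  Because the
  generative law *is* the discrete-choice model, conditional logistic
  regression is consistent for β_true and the estimator is testable by
  parameter recovery.  62 fixes at 1-h cadence give 61 strata of 1 case
  + 100 alternatives.

The covariate scale inside the generator is **declared**, not
estimated: centers (50 km, 0 m/s, 2 m/s) and scales (50 km, 3 m/s,
2 m/s) are fixed constants, so the truth does not depend on realized
sample moments (the interaction term makes β_true center-dependent, so a
truth defined on pooled z-scores would shift with every realization).
Recovery fits therefore reuse the declared scaling table; the pipeline's
default pooled z-scoring remains available and recovers the same signs
and approximate magnitudes.

Two recovery designs are used: the sequential track with its internal
choice sets retained (the realistic 61-stratum case — the conditional
likelihood of a sequential track is still the product of correct choice
probabilities), and i.i.d. strata with random start points
(`simulate_strata`) for large-sample checks, since a 1000-step track
would exit any finite study area.

**What passing tests show, and what they do not.**  Recovery, CV and
importance results on this system validate the *estimator and pipeline*
under a correctly specified model with smooth covariates.  Real
telemetry adds location error, irregular duty cycles, behavioural
heterogeneity, covariate misspecification, and alternative steps that
are not draws from the true availability law — none of which the
generator emulates.  Tests passing here do not certify field inference;
they certify that the machinery computes what it claims.

## Problem sizes and numerical conventions

The default verification runs use: 50 random small designs for the
likelihood-oracle check (10 strata × 6 steps, ≤3 terms); 100 replicate
61-stratum tracks for 2-SE coverage; 10 × 1000 i.i.d. strata for bias;
100 random ≤5×5 grids against an exhaustive (cost-bound-pruned,
exact) path enumeration; 1000 random triples for the wind identity; 80
independent null datasets (100 strata × 20 steps — 20 divides the 10
bins evenly, removing the binning bump) and 100 CV repetitions under
strong selection.  These sizes keep the full verification under a minute
on one core while holding Monte-Carlo error well inside every band.

Other conventions: spherical Earth R = 6371 km (ellipsoidal corrections
are negligible at 100-km steps); bearings are initial great-circle
bearings; turning angles wrap to (−180°, 180°] with reversals mapped to
+180°; haversine distances; collinearity screening flags |r| strictly
above 0.7 (with a 1e-12 guard) and is advisory only; thinning is greedy
from the first fix and idempotent; strata never span individuals.  One
global seed expands into per-stage generators via
`numpy.random.default_rng([seed, stage])`, making every stage
independently reproducible and every artifact byte-identical under
rerun.

## Known limitations

- The conditional-logit small-sample bias is visible at 61 strata
  (≈ 0.1–0.2 SE on the strongest coefficient); no Firth-type correction
  is applied, by design — separation and small-n fragility are reported,
  not masked.
- Nearest-layer wind matching can misattribute wind by up to half the
  layer interval; with 6-hourly layers and hourly steps this is the
  dominant annotation approximation.
- The least-cost path is isotropic: conductance ignores wind, so the
  "geographic optimum" is a water-avoidance benchmark, not an energy
  model.  An anisotropic (wind-dependent) cost surface is an obvious
  extension and deliberately out of scope.
- `simulate_track` errors if an entire candidate set falls outside the
  grid twice in a row; the default grid makes this unobserved in 600
  seeded tracks, but pathological configurations (tiny grids, huge
  steps) will trip it.
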