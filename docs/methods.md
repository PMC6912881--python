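# Methods

This note documents the models, defaults, numerical conventions and known
limitations of the `aridrange` pipeline, in the order the stages run.

## Raster model and geometry

All stages share one cell-centre-registered, axis-aligned grid
(`GridSpec`): x grows east, y grows north, row 0 is the northernmost row.
Cells are half-open — cell (i, j) covers
[x0 + j·dx, x0 + (j+1)·dx) × (y0 − (i+1)·dy, y0 − i·dy] — so every point
maps to exactly one cell; points on a shared edge belong to the
larger-index cell, and points on the grid's outer max-x/min-y boundary are
assigned to the last cell. Two grids are "aligned" only when all six
geometry fields match exactly.

Only nearest-neighbour resampling is implemented (`align_to_grid`): each
target cell takes the source cell whose centre is nearest its own centre,
ties toward the smaller row then column index; nodata propagates and target
cells outside the source extent become nodata. No reprojection is
attempted; degree grids are accepted for modelling but rejected by the
eikonal solver (below).

File formats: ESRI ASCII grids (square cells, 6 printed decimals — so a
write/read round trip is exact to 5·10⁻⁷) and single-band GeoTIFF written
through tifffile with the ModelPixelScale/ModelTiepoint tags, float32
payload, NaN-coded nodata and a GDAL_NODATA tag.

Survey sites that fall outside the grid or on nodata cells are excluded
from the design table with a logged count — the conventional treatment,
adopted here as an explicit choice.

## Distance to water (eikonal / fast marching)

DIST_F and DIST_S solve |∇d| = 1 with d = 0 on every water cell, using the
canonical first-order upwind fast-marching scheme: for a cell with minimum
accepted horizontal neighbour a and vertical neighbour b,

    ((d − a)/hx)² + ((d − b)/hy)² = 1,

taking the larger root when it is ≥ max(a, b), else the one-sided update
min(a + hx, b + hy). The priority queue breaks distance ties toward smaller
(row, column); the result is order-independent regardless (label-setting).
Nodata cells are impassable; unreachable cells carry an infinite sentinel
and are masked on export. Distances are in map units (the CLI converts to
km for metre grids). Sub-cell waterbody geometry is not reconstructed:
every water cell is initialised to d = 0.

The solver demands a projected grid. `GridSpec` carries no CRS, so the
check is a heuristic: an origin inside the lon/lat bounding box with cells
smaller than half a degree is treated as geographic and rejected with a
message asking for projection.

Numerical properties, verified in the tests against an exact lattice
Dijkstra oracle and the closed-form Euclidean distance:

* single-front sandwich: Euclidean ≤ FMM ≤ 4-connected graph distance
  (obstacles allowed). The Euclidean lower bound is a *single-front*
  property — where wavefronts from separate sources collide, the upwind
  update combines neighbours from different fronts and can dip a fraction
  of a cell below the exact min-distance on the collision ridge. The upper
  bound (FMM ≤ 4-connected Dijkstra) holds for any source set.
* the single-cell-initialised scheme is exactly scale-invariant
  (d_h = h·D on the integer lattice), so its relative error at a fixed
  *cell* radius does not change with resolution. Convergence is therefore
  stated for a fixed physical domain and a fixed physical exclusion radius
  (10 map units): refining a 201² unit grid to 401² halves the cell size
  and drops the L∞ relative error from ≈7.0% to ≈4.5%. Higher-order
  schemes or exact source-disk initialisation would reduce the constant;
  they are out of scope.

## Collinearity screening

Pairwise Pearson r computed at the survey sites (pairwise-complete, ≥3
complete rows required; zero-variance variables get r = 0 with a warning).
The filter is a greedy scan in an explicit priority order: accept a
variable iff |r| < 0.70 against every variable already accepted, else drop
it recording the first blocking partner. The priority list is a declared
input (defaulting to the design-table order) because choosing the survivor
of a correlated pair is ecological judgement, not an algorithm. The kept
set is maximal for the given order; the threshold 0.70 is the field's
standard collinearity rule of thumb. Screening at sites (rather than over
all raster cells) matches the modelling sample space and is the cheaper
convention; the alternative is one flag away for a user who wants it.

## Learners

All learners are scikit-learn-style estimators with a common contract —
`fit(X, y)` on a binary design table, `predict_suitability(X)` in [0, 1],
bit-identical refits under a fixed seed — and serialise to a documented
JSON schema. A plug-in registry admits further algorithms into evaluation
and consensus unchanged; true absences are used throughout (the survey
records them), never pseudo-absences.

* **Envelope (BIOCLIM/SRE).** Per-variable presence quantile interval
  [q, 1−q], linear interpolation of order statistics; score 1 iff every
  variable is inside its interval. Default q = 0.025 (the conventional 95%
  envelope).
* **Logistic GLM.** Standardised predictors (stored in the model so raster
  prediction is self-contained), optional squared terms (degree 2 is the
  pipeline default, giving unimodal response curves), IRLS with ridge
  λ = 10⁻⁸ on the normal equations, convergence when the largest
  coefficient change is < 10⁻⁸ (flagged otherwise). Linear predictors are
  clipped at ±30 for overflow safety. Under complete separation the fit
  converges to the ridge-pinned solution and sets a separation flag
  (|standardised β| > 10).
* **Bagged CART.** n_trees = 50 bootstrap trees (tree t seeded seed + t),
  greedy Gini splits over m_try = ⌊√p⌋ random variables per node,
  max_depth = 8, min_leaf = 5; split candidates are midpoints between
  consecutive distinct values, impurity ties resolve to the smallest
  threshold; a node splits only on a strict impurity decrease. Leaves hold
  presence fractions; the score is the across-tree mean.

## Evaluation and the gate

Calibration/test splits are uniform without replacement,
|calibration| = round(0.75·n), replicate r seeded seed + r; 10 replicates
by default. AUC is the rank-based Mann–Whitney statistic with midranks, so
ties contribute ½. τ* maximises sensitivity + specificity over candidate
cuts at midpoints between consecutive distinct scores plus an all-present
and an all-absent cut, with the classification rule "presence iff
score ≥ τ" and objective ties resolved toward the smallest τ (favouring
sensitivity); the achieved maximum is convention-invariant and is checked
against a brute-force scan. Evaluation uses the held-out rows only.
Quality labels: AUC fair = [0.7, 0.8), good = [0.8, 1]; TSS
fair = [0.4, 0.6), good = [0.6, 1). The admission gate is strict:
AUC > 0.8 and TSS > 0.45; the reported selection rate is rounded to the
nearest percent. An empty selection is legal and propagates as a
"no consensus possible" report, not an exception.

## Consensus, scenarios, importance

Each admitted model is binarized at its own τ* (≥ convention; future
projections reuse the calibration-time τ*). The consensus map records the
per-cell fraction of contributing (off-mask) members voting presence; a
cell enters the range map when strictly more than 2/3 of members agree —
"66%" is read as the IPCC likelihood band, i.e. exactly ⅔, configurable.
Scenario consensus pools |models| × |GCMs| members with equal weight and
applies the same cutoff. The pooled set is exactly the gate-admitted
models.

Importance of a variable is 1 − r between predictions from the original
design and one with that column permuted, averaged over three seeded
shuffles; computed on each model's calibration rows by default (matching
the model's training support) and averaged over admitted models. 1 − r is
reported unclipped, so values slightly above 1 are possible when the
permutation anti-correlates predictions; undefined r (constant
predictions) is recorded as 0 with a warning.

Range change classifies each off-mask cell by its (current, future) bit
pair (codes: 0 stable-unsuitable, 1 gain, 2 loss, 3 stable-suitable, union
of nodata masks applied). Gain% and loss% are relative to the *current*
suitable cell count — so a complete collapse is exactly −100% — and
net = gain% − loss%. An empty current range yields NaN percentages with a
warning rather than an error.

## Virtual species simulator

The simulator exists to make the whole chain falsifiable: it generates the
study conditions and retains the truth.

* **Climate surfaces** (120×120 grid of 1-km projected cells by default):
  each variable is a directional gradient plus Gaussian-smoothed white
  noise; when a target correlation matrix is given (defaults: strong
  MAT–MTCM 0.8, PWM–PCQ 0.6, moderate MDR–ISO 0.5, weak negative
  temperature–precipitation), the per-variable basis fields are
  orthonormalised across cells and mixed through the Cholesky factor, so
  realised correlations match the targets almost exactly; each surface is
  then rescaled to a basin-realistic range (e.g. MAT 1.3–9.8 °C,
  MTCM −25…−12 °C, PWM 10–35 mm). A non-positive-definite target matrix is
  rejected.
* **Water masks:** rivers as one-cell-wide 4-connected west-to-east random
  walks, lakes as random ellipses; DIST_F/DIST_S then come from the real
  eikonal solver, in km.
* **Species truth:** logistic in standardised predictors,
  π = expit(β0 + Σβz + Σγz²); the default two-variable species
  (β0 = −0.5, βMAT = 2.0, βPWM = 1.5) gives ≈0.4 prevalence. The logistic
  form intentionally matches one implemented learner, so recovery failures
  indict the pipeline rather than model misspecification; the γ terms
  provide a Gaussian-response (misspecified) variant. Truth maps use
  π > 0.5; standardisation constants always come from the *current*
  landscape so future stacks shift suitability instead of being
  re-standardised away.
* **Surveys:** n = 2,500 sites by default, distinct cells, uniform or
  transect (evenly spaced west–east rows, road-survey style); presence ~
  Bernoulli(π · detection), detection 1 by default.
* **Scenarios:** additive per-variable deltas (default +2 °C / +2 mm on
  the four temperature/precipitation drivers for the 2050s), optional
  smooth spatial component, and per-GCM smooth jitter fields (amplitude
  0.3, three virtual GCMs) emulating between-GCM spread; distance and
  topographic layers are never perturbed. The "true" future range is
  evaluated under the jitter-free ensemble-mean delta.

Everything is deterministic from one top-level seed (sub-stage seeds are
derived constants or CRC-derived label hashes), to the byte.

What the simulator does **not** emulate: spatially autocorrelated survey
effort or detection error, non-stationary climate deltas from real GCM
physics, landcover/soil constraints, dispersal limitation, and biotic
interactions. Passing recovery tests therefore demonstrates that the
pipeline's statistics and plumbing are correct under known truth — not
that any real species' projection is accurate.

## Problem sizes and thresholds used in validation

The test suite and acceptance script run the end-to-end recovery at the
default 120×120 landscape with 2,000 survey sites, three learners × 10
replicates and three virtual GCMs — sizes at which the committee's
behaviour (selection rates around 50–70%, recovery Jaccard ≈ 0.85–0.9) is
stable across seeds — and score recovery as the Jaccard overlap between
the 2/3-consensus map and the truth map, requiring ≥ 0.75. Determinism is
asserted by rerunning the full pipeline and comparing report JSON
byte-for-byte (timestamp excluded). Oracle agreements (rank AUC vs
exhaustive pairwise comparison; τ* objective vs exhaustive cut scan) are
required to 10⁻¹².

## Known limitations

* One suitability scale: score-averaging (probability-weighted) ensembles
  and GCM weighting are out of scope; the committee is strictly one
  member, one vote.
* The FMM is first-order; its constant-factor diagonal bias (~7% at 10
  cells from a point source) is inherent to the stencil.
* The envelope learner emits hard 0/1 scores; its AUC is
  correspondingly coarse and it rarely clears the gate — which is the
  gate working as designed, not a defect.
* No spatial cross-validation: split replicates are random, so spatial
  autocorrelation can flatter held-out scores on strongly autocorrelated
  landscapes.
* No reprojection; inputs must share one grid or be nearest-neighbour
  alignable.
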