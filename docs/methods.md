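# Methods

## Model and procedure

`markersig` ranks features that discriminate a selected sample subset A
from a reference B.  In "A vs Rest" mode B is the complement of A; in
"A vs B" mode samples in neither group are ignored entirely.

**Step 1 — distributional pre-filter.**  Each feature's values in A and B
are summarized by their empirical mean and standard deviation, and the
feature receives the closed-form 2-Wasserstein distance between the two
univariate Gaussians fitted to those moments,
W = √((μ_A−μ_B)² + (σ_A−σ_B)²).  The Gaussian assumption is only a
ranking device: W is used as a scalar "how different are these two
distributions" score, and its two limits (|Δμ| for equal variances, |Δσ|
for equal means) make it sensitive to both location and scale shifts.
The order of the Wasserstein metric is a design choice — the elementary
closed form for Gaussians is the 2-Wasserstein distance, so W2 is used.
Standard deviations use divisor *n* (population, ddof = 0): the closed
form needs an empirical σ and the population estimator is defined even
for singleton groups; `ddof` is exposed for users who prefer n−1.  The
pre-filter keeps the `n_prefilter` features with the largest W
(descending, ties broken by ascending feature index via a stable sort).
`n_prefilter` defaults to 500 — comfortably above the display size of
100 — and is configurable.

**Step 2 — MCC-optimal thresholds.**  For each kept feature, candidate
thresholds are the midpoints between consecutive distinct sorted values.
When a feature has more than `max_grid` (default 100) midpoints, the
candidate set is subsampled to `max_grid` quantile-spaced midpoints; this
bounds the memory of the vectorized threshold × sample scan while
tracking the data's own quantiles.  Both polarities are scored — predict
A where value > θ ("up_in_A") and where value < θ ("down_in_A") — so
down-regulated markers compete on equal terms; the reported direction
tells the user which way the marker moves.  Since thresholds are strict
midpoints, no sample value ever equals θ and the down-polarity confusion
matrix is exactly the complement of the up-polarity one.  Ties in MCC
are broken deterministically by smaller θ, then by the up polarity.
Degenerate cases are fixed by convention: a constant feature returns
(θ = the constant, up_in_A, MCC 0); an MCC whose denominator has a zero
factor is 0.

**Final ranking.**  Entries are ordered by MCC descending, ties by W
descending, then feature index, and truncated to `n_top` (default 100)
features — a set large enough for downstream enrichment-style analyses.
How the two steps combine into a display order is a genuinely open
choice; MCC-first was chosen because step 2 is the sharper
discrimination measure, and the key is documented so ties are
reproducible.

**Oriented signatures.**  The selected samples' embedding coordinates
are projected onto a user-drawn arrow, t_i = (p_i−s)·(e−s)/‖e−s‖², with
t outside [0, 1] kept for points beyond the segment.  Features are
ranked by Pearson correlation with t; the default order is signed r
descending (matching "most positively correlated along the arrow
first"), with an `absolute` option for bidirectional gradients.
Zero-variance features (or a zero-variance projection) get r = 0 by
convention.  At least 3 selected samples are required.

## Selection geometry

Lassos are implicitly closed polygons with ≥ 3 vertices and non-zero
area.  Point-in-polygon uses even-odd ray casting with an explicit
on-segment test; boundary points count as inside, which makes the
decision deterministic instead of dependent on floating-point flicker.
Self-intersecting lassos follow even-odd semantics and are not repaired.
The independent test oracle is a winding-number implementation.

The 3D lasso uses an orthographic camera: points are rotated by an
orthonormal 3×3 view matrix (checked to 1e-9), the first two view
coordinates are tested against the polygon, and depth is ignored.
Whether the interactive tools this mirrors use a perspective camera is
not documented; orthographic is the simplest model under which a 3D
lasso behaves exactly like a 2D lasso on the rotated coordinates, and
the identity view reduces to the 2D case by construction.  Embeddings
with more than 3 dimensions are handled by picking 2 or 3 distinct axes.

Selections combine by element-wise boolean algebra (union, intersection,
difference = A AND NOT B) with provenance strings recording the
expression.

## Baselines

The t-test is Welch's (unequal variances), two-sided, the safer default
for heteroskedastic omics features; zero-variance features are assigned
p = 1 (never NaN) so rankings are total, and p-ties are broken by |t|.
The Wilcoxon rank-sum test uses the exact null distribution when both
groups have ≤ 8 samples and the feature has no ties, and the
tie-corrected normal approximation otherwise.  COSG is implemented as
described for the two-group case: the ideal marker of the target group
is its binary membership indicator over samples, and each feature column
is scored by cosine similarity to it (zero-norm features score 0).  The
published COSG's λ regularization and multi-group penalty are out of
scope.  Both tests are computed with scipy's reference routines behind
the module's ranking surface; the test suite checks them against
hand-written formula/enumeration oracles.

## Benchmark harness

For every cluster label: rank features for label-vs-rest, take the top k
(k = 1..20 by default), train a classifier on a stratified split and
report the Matthews correlation coefficient on the test set.  The split
assigns round(train_frac · class size) samples of each class to the
train set (train_frac default 0.7), keeping at least one train and one
test sample per class, so class frequencies are preserved at rounding
granularity.  Feature ranking sees the training split only — the
protocol description is ambiguous on this point, and selecting on the
full data would leak test information into the feature choice;
`select_on_full=True` mimics the alternative.  The default classifier is
an RBF-kernel SVM with library defaults; it is pluggable (KNN, random
forests, ...).  Features are standardized with train-set mean/sd before
fitting because the RBF kernel's default scale is sensitive to feature
magnitudes; a flag disables this.  Splits repeat `reps = 10` times with
seeds seed+rep; clusters with fewer than 4 samples on either side are
skipped with a warning.  Aggregates (mean ± sd of MCC per method and k)
are recomputed from the per-repetition records, never stored separately.

## Synthetic data

The generator emulates the structure the methods assume: clusters of
samples in configured proportions; per-cluster planted markers, either
mean shifts (Δμ in units of the base-noise σ, default 3) or variance
shifts (σ ratio, default 3); exchangeable standard-normal null features;
and a PCA embedding (2 or 3 components of the standardized matrix)
stored as `X_pca`.  Defaults are 300 samples × 500 features, three equal
clusters, five mean-shift markers each — small enough to run in seconds,
large enough that marker recovery is a meaningful statistical event.
The `lognormal-counts` mode applies round(exp(z)) to the Gaussian latent
matrix to mimic count-like skewed data; planted effects are defined on
the latent scale there.  The trajectory generator draws u ~ Uniform(0,1)
per sample, builds correlated features u + σ_n·ε with σ_n chosen so the
theoretical Pearson correlation equals the configured value
(σ_n = σ_u √(1/ρ² − 1), σ_u = 1/√12), and stores an embedding whose
first axis is u, so an arrow along axis 1 recovers u exactly.  One
master seed drives independent sub-streams per block.

What the generator does *not* emulate: batch effects, dropout, realistic
gene–gene covariance, or library-size variation.  Passing tests
therefore demonstrate correctness of the algorithms under their stated
assumptions, not performance on real data.

## Numerical choices and limitations

- TSV matrices are written with `%.17g`, which round-trips IEEE doubles
  exactly; reading uses round-trip float parsing.
- The on-segment tolerance for polygon boundaries is 1e-12 relative to
  edge length.
- `n_prefilter` larger than the number of features is clamped with a
  warning; `n_top` must not exceed `n_prefilter`.
- Matrices may be scipy-sparse; group statistics and COSG use sparse
  arithmetic, while the per-feature threshold scan and oriented
  correlations densify only the selected row block.
- MCC and Pearson conventions (0 on degenerate denominators) make
  rankings total but mean a score of 0 is ambiguous between "no signal"
  and "degenerate input"; the direction/threshold fields disambiguate in
  signature output.
- Which matrix layer to use when an `.h5ad` stores several is
  unspecified upstream; the main matrix (`X`) is used.
- The threshold grid cap trades exactness for memory on features with
  more than `max_grid` distinct values; with default settings the scan
  is exact for groups of up to 101 samples and quantile-approximate
  beyond.
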