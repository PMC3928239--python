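# Methods

## The benchmark design

The central object is a pooled, multi-dataset cohort of pre-treatment tumour
expression profiles with clinical annotation and a binary pathological
complete response (pCR) endpoint.  Two families of predictors are compared
per subtype *s*:

* **subtype-specific**: trained on training samples of *s* only;
* **generic**: trained on training samples of all subtypes.

Both are validated on the same validation samples of *s*, and performance is
the Mann–Whitney AUC: P(score of a random responder > score of a random
non-responder), with tied pairs counted 1/2.  The tie convention matters — it
is what makes a predictor whose selected features are constant within a
subgroup score *exactly* 0.5 there, the degenerate case the benchmark is
designed to expose.

### Double-loop cross-validation

Outer loop (default R = 15 repetitions): a stratified split assigns
round-half-up(2n/3) of each stratum to training and the rest to validation.
Strata are (refined subtype × response) cells — the refinement (HER2+/ER− vs
HER2+/ER+) is included so the subgroup analyses see balanced response rates
on both sides; a cell below the minimum stratum size (default 3) is merged
with its subtype's other response cell.  One split per repetition is shared
by every scope and configuration, so a specific-vs-generic AUC difference
can never be an artefact of different validation samples.  This sharing is a
deliberate variance-reduction choice; an alternative design would draw
independent splits per scope.

Inner loop: on the training side only, stratified 3-fold cross-validation
evaluates each candidate feature count n (expression grid
{1, 2, 5, 10, 20, 30, 50, 100}, clinical grid {1..6} — spanning the sizes
practitioners publish for expression signatures and exhausting the six
clinical features); the ranker is refit on each fold's training part.  Mean
fold AUCs are rounded to 1e-12 and ties go to the smallest n (parsimony).
The winning n is used to refit ranker + classifier on the full training
side.  The decision tree skips the inner loop; its impurity-driven splits
are its own feature selection.

The 16 configurations per modality are 3 rankers × 5 classifiers plus the
tree.  Failed cells (e.g. a single-class validation subgroup) are recorded
with a reason and excluded pairwise from downstream t-tests.

### Comparison statistics

Per (subtype, modality) the best configuration by mean AUC is picked within
each scope (ties: fewer features, then lexicographic name), and the two
R-length AUC distributions are compared with a two-sided Welch t-test
(unequal variances assumed; nothing justifies pooling them).  Bonferroni
multiplies the raw p by the declared family size — by default the number of
(subtype × modality) comparisons in the run — and significance is adjusted
p < 0.05.  A paired alternative (justified by the shared splits) is exposed
as an option; the default stays unpaired, treating the two distributions
symmetrically.

## Harmonization

Datasets from different institutes are combined after per-gene median
centering to a reference dataset.  Because subtype mix and response rates
differ between institutes, raw medians are not comparable; each dataset's
median is computed on its largest subset whose (refined subtype × response)
composition is proportional to a common target.  The default target is the
reference dataset's own composition restricted to cells present in every
dataset (renormalized) — a cell some dataset cannot serve at all cannot be
matched on.  Scaling: with target proportions p_c and available counts a_c,
the subset takes floor(s·p_c) per cell with s = min_c a_c/p_c, which is the
largest proportional subset up to integer rounding.  Surplus cells are
down-sampled uniformly with a recorded seed.  Centering subtracts, per gene,
(balanced median of the dataset − balanced median of the reference), leaving
the reference untouched; it is idempotent given the same seed.

Probe-level matrices collapse to gene level by keeping the probe with the
highest standard deviation (ddof = 1) across the pooled post-centering
sample axis; ties break to the lexicographically smallest probe id.

## Feature rankers

* **WMW**: two-sided rank-sum p-value per feature, ascending.  Exact null
  when both classes have ≤ 10 samples and the feature is tie-free; otherwise
  the normal approximation with tie and continuity correction.  Constant
  features get p = 1 and rank last.
* **WMW-uncorrelated**: greedy scan of the WMW ranking; a feature is dropped
  iff its |Pearson r| with an already-kept feature exceeds 0.75, so each
  correlated cluster keeps its best-ranked representative and the top
  feature is never removed.  Constant features (undefined r) are treated as
  uncorrelated.
* **BWR**: Σ_k n_k(μ_kj − μ_j)² / Σ_k Σ_{i∈k}(x_ij − μ_kj)², descending.
  Zero within-group scatter with non-zero between yields +inf (ranked
  first); a fully constant feature scores 0.
* **Information gain**: H(y) − H(y | feature) in nats; continuous clinical
  features (age) are discretized into 3 equal-frequency bins first (a
  coarse-but-stable default for cohorts of a few hundred samples).
* **CFS**: forward best-first subset search on the merit
  k·r̄_cf / √(k + k(k−1)·r̄_ff) with symmetrical uncertainty as both the
  feature–class and feature–feature correlation; up to 5 consecutive
  non-improving expansions are tolerated.  The ranking is the inclusion
  order of the best subset found, with unselected features appended by
  individual class-SU.  Because inclusion order is not monotone in merit,
  this ranking is flagged *ordinal*: the order is authoritative and the
  score column is informational.
* **ReliefF**: deterministic sweep over every instance (no subsampling, for
  reproducibility) with k = 3 nearest hits and misses under a normalized
  Manhattan distance (categorical difference 0/1, continuous |a−b|/range);
  weight updates are mean miss-difference minus mean hit-difference,
  averaged over instances.

Everywhere, score ties break to the lexicographically smallest feature id,
and all rankers are permutation-equivariant in the sample order.

## Classifiers

All six consume a numeric matrix: ER/PR/HER2 as 0/1, grade and TNM stage as
ordered integers, age continuous.  Clinical-modality analyses are
complete-case: samples missing any of the six features are dropped from that
modality only.

* **NB** — hand-rolled mixed naive Bayes: Gaussian class-conditionals for
  continuous features (variance floored at 1e-9 × the largest feature
  variance), Laplace-smoothed (α = 1) level frequencies for categorical
  ones; an unseen level contributes α/(n_k + α(L+1)).  Score = posterior
  P(pCR | x).
* **NM** — nearest mean in Euclidean space; score = d(x, μ_noPCR) −
  d(x, μ_pCR); the decision boundary is the perpendicular bisector.
* **3NN** — brute-force Euclidean 3-nearest-neighbour; score = fraction of
  responders among the neighbours.
* **LREG** — logistic regression (lbfgs, C = 1); score = fitted probability.
  The mild default regularization keeps perfectly separated small training
  sets finite without affecting score ordering.
* **SVM** — linear kernel, C = 1, features standardized inside the
  predictor; score = signed decision value (hard labels would quantize the
  ROC).
* **TREE** — CART with entropy impurity and minimum leaf size 2; score =
  Laplace-smoothed leaf responder proportion (c₁+1)/(c₀+c₁+2), avoiding
  degenerate 0/1 scores.

Fits are deterministic; the tree's internal tie-breaking is pinned to a
constant random state.  Trained predictors serialize (pickle with a format
version) and round-trip to identical scores.

## The synthetic generator

`simulate.generate` emulates: three datasets with per-gene additive batch
shifts ~ N(0, τ = 0.3); sample subtypes drawn from refined-cell proportions
(defaults 45:37:199:113 over HER2+/ER−, HER2+/ER+, Luminal, TN — totalling
394 samples as 132+131+131); pCR drawn per cell (defaults 25/45, 6/37,
14/199, 42/113) through a logistic model whose linear predictor adds
standardized age/grade/stage terms with per-subtype log-odds coefficients;
ER/HER2 deterministic given the cell, PR equal to ER with flip probability
0.1; and expression = N(0, 1) baseline + batch shift + marker-module shifts
(20 ER-like and 20 HER2-like genes at +1.5 log2 for marker-positive
samples) + response-signal shifts (shared or subtype-private, default
+1.0 log2 — an effect comfortably detectable at n ≈ 100, since per-gene
power, not microarray realism, is what the pipeline tests need).

Presets:

* `null` — no signal, no batch shift; calibration scenarios.
* `shared_signal` — 10 genes shifted in responders of all subtypes.
* `subtype_private_signal` — 10 genes shifted in TN responders only.
* `confounded_marker` — no response-informative genes; the between-cell
  pCR-rate differences make ER/PR/HER2 strongly predictive pooled while
  constant within each cell; age/grade/stage carry log-odds 1.2/1.0/0.8
  within the HER2+ cells and nothing elsewhere, so the pooled ranking
  buries them below the receptor features.  Coefficients are sized so the
  within-subgroup signal is clearly detectable from ~30 training samples —
  the mechanism, not a marginal effect, is what the scenario is for.
* `rare_minority` — shared signal (10 genes, 1000 total) with the Luminal
  cell's 7 % response rate; the specific Luminal predictor trains on ~9
  responders, the generic one on ~58.

What the generator does **not** emulate: probe-level noise, GC-RMA
artefacts, intensity-dependent variance, intrinsic (PAM50-style) expression
subtypes, or correlated gene modules beyond the marker blocks.  Passing
tests therefore demonstrate that the pipeline recovers the designed
phenomena under idealized Gaussian additive structure — not that the same
effect sizes or significance levels would be observed on real microarray
cohorts.

## Numerical choices and degenerate inputs

* Composition percentages round half-up to integers.
* Balanced-subset medians compared at 1e-9; centering idempotence at 1e-9.
* Inner-loop mean AUCs rounded to 1e-12 before the argmax.
* Inner folds are redrawn (new seed, ≤ 10 attempts) if a fold lacks a class.
* All seeds derive from one master seed; repetition r uses master + r.
* A validation subgroup with one response class is a recorded failed cell.
* Missing AUC cells are excluded pairwise from t-tests with counts reported;
  fewer than two values on a side marks the comparison untestable.
* The minimum subgroup size for stratified splitting is a parameter rather
  than a hard-coded exclusion of HER2+/ER+ — small refinements merge into
  their subtype stratum and remain analyzable or not on their own merits.

## Problem sizes

Default study size is 394 samples over three datasets, matching the scale
the benchmark is meant for.  Bundled analyses and tests run the double loop
with one or a few configurations on a few hundred samples and 100–1000
genes, which exercises every code path at a few seconds to ~10 s per
scenario; full 16-configuration runs scale linearly in configurations.

## Known limitations

* CFS's appended (non-selected) tail is ordered by individual class-SU,
  which ignores redundancy among appended features.
* The SVM's SMO solver is training-order invariant only to its convergence
  tolerance (~1e-3 on decision values).
* The tree stands in for C4.5-style implementations with CART + entropy;
  pruning behaviour differs, leaf-proportion scores do not.
* Welch's test treats the R repetition AUCs as independent; they share
  samples across repetitions, so p-values are optimistic in the usual
  repeated-cross-validation sense and should be read comparatively.
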