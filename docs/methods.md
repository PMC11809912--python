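# Methods

## Problem setting

Given a labeled tabular dataset whose classes are imbalanced (majority count
N_Cmax, minority counts below it), the package produces a balanced dataset for
classifier training. The core assumption throughout is geometric: the samples
of one category occupy one or two concentrated regions of feature space, so a
noise-removal step that leaves a category scattered across many small clusters
has removed the wrong points. All distances are Euclidean, and every
density-based step presumes features on a common scale — min-max
normalization to [0, 1] is applied first, which is what makes an absolute
radius like ε = 0.1 transferable across datasets.

## Pipelines

**SMOTE (stages 1 and 3).** Each below-target class is brought up to the
target by repeatedly drawing a random class member x, one of its K_SMOTE
nearest same-class neighbors x_nn, and a fresh β ~ U[0, 1), and appending
x + β·(x_nn − x). The neighbor table is computed once over the *original*
class members, so synthetic points never become parents; this is canonical
SMOTE semantics and keeps the output distribution stable. A literal reading
in which each inserted point joins the candidate pool is available as
`grow_pool=True` for comparison. Distance ties in neighbor queries break to
the lower row id; a single seeded generator threads all draws in a fixed
order (sample, neighbor, β), so outputs are bit-reproducible.

**DBSCAN.** A point is core when its closed ε-ball (self included) contains
at least N points; a non-core point within ε of a core point is border; the
rest is noise. Clusters are connected components of the core graph with
border points attached. Three conventions the standard description leaves
open are fixed deterministically: the ball is closed (≤ ε), a border point
reachable from several clusters joins its *nearest* core point's cluster
(ties to the lower cluster id), and cluster ids are numbered by the lowest
row index they contain. These choices make the partition invariant under row
permutation up to relabeling, which the tests verify against an independent
breadth-first-search implementation.

**Constrained noise removal (`crn_smote` stage 2).** Per non-majority class,
DBSCAN runs at ε = ε₀, ε₀ + δ, … and stops at the first radius where the
number of clusters c satisfies 0 < c ≤ N_cluster; the points that are still
noise at that radius are removed. Termination is structural: once ε reaches
the class diameter, every point is core and c = 1, so the loop always exits
for classes of at least N points. Guards: classes smaller than N (all points
would be noise at every radius, making the bound unsatisfiable) and classes
whose cleanup would leave fewer than 2 points (the final SMOTE needs two
parents) pass through unfiltered with a logged warning rather than being
destroyed. The stage-2 DBSCAN sees the full SMOTEd class matrix (originals
plus stage-1 synthetics); the majority class is exempt and its rows appear
verbatim in the output.

**Fixed-radius baseline (`rn_smote`).** Identical skeleton, but stage 2 is a
single DBSCAN pass per class at a fixed ε — supplied, or derived per class
from the K-distance heuristic (the 0.90 quantile of each point's distance to
its k-th nearest neighbor, k = N) — and every surviving cluster is kept, no
matter how many there are.

**Tomek and ENN hybrids.** `smote_tomek` deletes both members of every Tomek
link (mutual opposite-class nearest neighbors over the whole balanced
dataset); a `removal="majority"` flag restricts deletion to the majority
member. `smote_enn` removes every sample whose label is not the strict
majority among its 3 nearest neighbors (vote ties count as disagreement).
Both may leave counts unequal; that is inherent to these cleanups.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_cluster` | 1 | largest acceptable cluster count per class after cleanup (1 or 2 are the meaningful settings) |
| `eps0` | 0.1 | initial DBSCAN radius, on [0, 1]-scaled features |
| `delta` | 0.05 | radius increment; ≤ ~20 steps span a unit-scaled space |
| `min_samples` (N) | 5 | core threshold, self included |
| `k_smote` | 5 | SMOTE neighbor count; the evaluation grid sweeps 4, 5, 6 |
| ENN k | 3 | classic editing convention |
| K-distance quantile | 0.90 | fraction of points whose neighborhood is denser than the chosen ε |

δ = 0.05 and the 0.90 quantile are package choices where the procedure
specifies only "a small positive value" and "empirical"; both are exposed in
the configuration objects.

## Evaluation protocol

Stratified k-fold cross-validation (default 10 folds). Stratification is
deliberate: with a 167-sample minority and 10 folds, plain k-fold risks test
folds missing a class entirely. Within each fold, min-max statistics are
fitted on the training rows only and applied to the test rows, the training
portion alone is resampled (seed = harness seed + fold index), a classifier
is fitted at its library defaults (RBF-kernel SVM, random forest, AdaBoost
behind a thin adapter; only the RNG is pinned), and the untouched test fold
is scored. Binary datasets use the minority class as the positive class;
three-class datasets use macro averaging, with κ and the multiclass MCC
computed from the full table (both reduce exactly to the binary formulas at
m = 2). Zero denominators yield 0 in every metric. The no-resampling
baseline is computed once per classifier and repeated across the K_SMOTE
grid, since it does not depend on K_SMOTE.

## Synthetic data

The generator draws each class from a 1- or 2-component isotropic Gaussian
mixture and replaces a configurable fraction of each class's rows with
uniform draws over a box spanning all centers ± 3 spreads — outlier-like
points carrying a class label they do not geometrically belong to, the
failure mode SMOTE amplifies and stage 2 exists to remove. Class counts are
honored exactly and everything is deterministic in the seed. Benchmark-shaped
datasets reproduce the class counts of four public imbalance benchmarks
(1055 = 699/356, 748 = 570/178, 583 = 416/167, 1014 = 406/336/272); the
three-class fixture places its two minority classes as heavily overlapping
two-component mixtures (spread 0.30 in a 2-D unit-scaled space, 5% noise),
calibrated once so that a fixed ε = 0.1 fragments at least one minority
class into more than two clusters at every seed — the pathology the
constrained loop is designed to repair — and then frozen.

What the generator does **not** emulate: the real benchmarks' feature
distributions, dimensionalities, discrete/ordinal features, or
feature-label dependencies. Passing tests therefore demonstrate the
pipelines' contracts (balance, majority preservation, the cluster bound,
oracle-exact primitives) and the *direction* of the constrained pipeline's
advantage on data with this noise structure, not the magnitudes any
particular real dataset would show. On the synthetic geometry the κ gap
between the constrained and fixed-radius pipelines is small (medians within
a few thousandths), since both remove most of the same injected noise;
real data with stronger fragmentation can be expected to differentiate them
more.

## Numerical and design choices

- Majority-class ties break to the earliest label in sorted order; the same
  rule picks the minority (positive) class in the harness.
- Constant features min-max-normalize to 0, avoiding division by zero.
- Values outside the training range normalize outside [0, 1] in test folds;
  that is intentional (no clipping).
- Missing values are rejected at load with the offending row and column
  named; no imputation is attempted.
- CSV writing uses shortest-round-trip float formatting, so a write→load
  cycle reproduces features bit-exactly.
- Pipeline seeds: stage-1 SMOTE uses `seed`, stage-3 `seed + 1`, so the two
  oversampling passes are independently reproducible.
- Problem sizes in tests and the acceptance script (datasets of ≤ ~1100
  rows, 100 oracle instances of ≤ 80 points, 50 constrained runs, five
  cross-validation seeds) were chosen to exercise every guarantee at the
  benchmarks' native scale while keeping a full run in the minutes range.

## Known limitations

- O(n²) distance matrices cap practical dataset size at a few thousand rows;
  no spatial indexing is attempted.
- The cluster bound is enforced per class independently; nothing prevents
  two different classes' surviving clusters from overlapping.
- `n_cluster` is a user choice (1 or 2), not inferred from the data.
- Only numeric features are supported; categorical encoding is out of scope.
- The harness reports no significance tests between methods, only per-fold
  and mean scores.
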