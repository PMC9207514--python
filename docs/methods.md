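# Methods

## Model

A flexible neural tree (FNT) is a rooted tree classifier. Terminal nodes
emit one input feature each; an internal node of arity `n` holds weights
`w_1..w_n` and activation parameters `(a, b)` and computes
`y = exp(−((Σ w_j·child_j − a)/b)²)`. Every internal output therefore lies
in `(0, 1]` in exact arithmetic; in float64 the Gaussian underflows to 0
once `((net−a)/b)² > ~745`, which is why the trainer keeps `b` bounded
away from zero (see below). The root is always an operator — the single
output neuron — and its score is thresholded strictly (`> 0.5` by default)
into related/unrelated.

All parameters of a tree are flattened into one vector for the optimizer:
operator nodes in pre-order, each contributing its weights followed by
`a` then `b`. The layout is a package convention (any fixed ordering
works); extraction and injection round-trip losslessly, and any injected
`b` with `|b| < 1e−8` is pushed to `±1e−8` to keep the activation finite.

## Structure search

Topologies are derivation trees of the context-free grammar
`s → exp`, `exp → op_k exp^k` (one rule per admissible arity k),
`exp → var`, `op_k → +_k`, `var → x_i`. Only the prefix production form is
used; an infix two-operand rule would be redundant for tree construction.
Derivation is top-down, left-to-right, with productions chosen uniformly;
a derivation whose induced FNT depth exceeds the bound is discarded and
regenerated (capped at 1000 attempts — at the default depth 5 and arities
{2,3,4,5} roughly 1–2 % of free derivations survive, so the cap is
generous). Depth accounting is on the induced FNT (root operator = level
1, terminals count as a level), not on raw derivation levels, so the
configured `max_depth = 5` bounds the classifier itself.

Genetic operators: tournament selection of size 3 (lower RMSE wins, ties
broken by population index), subtree crossover at a non-terminal label
present in both parents, and mutation by regrowing a uniformly chosen
non-terminal subtree within its remaining depth budget. An offspring that
would exceed the depth bound — or whose root would become a bare terminal —
is replaced by its unmodified parent. One elite is copied unchanged each
generation. Rates default to crossover 0.8, mutation 0.2, elitism 1; these
are not prescribed by the underlying method and are config-exposed.

## Parameter search

The salp swarm algorithm minimizes the fitness over a per-tree box. The
leader (first salp) moves around the food position `F` by
`F ± c1·((Xmax−Xmin)·c2 + Xmin)` with `c2, c3 ~ U[0,1]` redrawn per
dimension and `c1 = 2·exp(−(4t/T)²)`. Followers update sequentially to the
midpoint of their own and their predecessor's (already updated) position.
The printed form of the follower rule is typographically ambiguous in the
method's source description ("X_ij − X_ij−1 / 2"); this package adopts the
midpoint `(X_j + X_{j−1})/2`, which is what the Newton's-law derivation
with unit time step and zero initial velocity yields in the original SSA
literature. Positions are clamped (not reflected) to the box after every
move; the food position is best-so-far, so the fitness trace is monotone
non-increasing by construction.

Parameter bounds default to weights in `[−1, 1]`, centers `a` in `[0, 1]`
(features are scaled to `[0, 1]`, so admissible `net` values for
moderate-weight trees live near this range), and widths `b` in
`[0.01, 1]` — strictly positive so the activation is well-conditioned.

## Hybrid schedule

The interleaving of structure and parameter search is a design choice of
this package (the underlying method specifies only population 30 and depth
5). Each GP individual receives a short, warm-started swarm polish
(default 10 salps × 20 iterations) with its current parameter vector
seeding the swarm — polish therefore never worsens an individual, and the
elite's recorded fitness is exact, which makes the per-generation best
fitness trace monotone. After the configured number of generations the
best structure gets a deeper run (default 30 salps × 100 iterations),
again warm-started. Training fitness is the RMSE of the continuous tree
output against the 0/1 labels — the standard choice in the FNT
neuroevolution literature; the underlying method leaves its fitness
function unspecified. Min-max feature scaling is fitted on the training
rows only and stored with the model; constant columns map to 0 and
out-of-range prediction inputs are clipped into `[0, 1]`.

## Negative-sample selection

`T(A,B) = |A∩B| / |A∪B|` on fingerprint bit sets, with `T = 0` when both
sets are empty (avoids 0/0). Each pool decoy's summed similarity to all
`m` positives is computed by the literal double loop; decoys are sorted
ascending with a stable sort, so ties resolve in input-file order and
reruns are byte-identical. Exactly `ratio·m` decoys are returned (default
ratio 2); smaller pools raise an error naming the required and available
counts. The fingerprint family used for similarity defaults to ECFP6 but
any consistent-width fingerprint set is accepted.

## Featurization

ECFP6 = Morgan circular fingerprint, radius 3, folded to 2048 bits. MACCS:
RDKit emits 167 bits with index 0 as unused padding; bit 0 is dropped so
vectors have exactly 166 entries. The RDKit 2D panel takes whatever
descriptor list the installed RDKit version exposes (210 here);
non-finite values are imputed to 0 with a logged warning. Exact
reproduction of a particular 208-descriptor panel or the 1,613-feature
macrocycle set is out of scope — such tables are consumed through the
CSV loader, which validates numeric cells and unique ids.

## Evaluation

Confusion metrics follow the strict `score > threshold` rule; a metric
with a zero denominator is reported as 0 and flagged in
`MetricsReport.undefined` rather than NaN, keeping reports
machine-readable. AUC is the rank-based (Mann–Whitney) statistic with
average ranks for ties; it is cross-checked against an independent
pair-enumeration oracle and against scikit-learn in the test suite.
Cross-validation is stratified (fold class ratios within ±1 sample),
seeded, with the fold assignment persisted. Method ranking assigns rank 1
to the best method per dataset column with mid-ranks for ties and averages
across columns; the ranking metric is AUC by default and selectable. The
ratio experiment reuses the selection + CV machinery per ratio and reports
per-ratio errors without aborting the sweep.

## Synthetic data

The generators emulate the *structure* the method assumes, not real
chemistry. Fingerprint classes draw bits independently from per-class
profiles (a high-probability block of 24 bits per class over 128, on-rate
0.6 vs background 0.02), giving within-class Tanimoto similarity above
between-class — like congeneric actives vs decoys — but with no bit
correlations, no physicochemical property matching, and no size
distribution of real libraries. Decoy pools copy a random positive's bits
and replace a per-decoy fraction of them with bits the positives never
use; the fraction ramps linearly from the `dissimilarity` parameter to 1
across the pool, so `dissimilarity = 1` yields fully disjoint bit sets
(summed similarity 0) and smaller values give the graded ordering the
selection algorithm must recover. Continuous fixtures are two isotropic
Gaussian blobs (default 60 + 60 points in 8 dimensions, 4 pooled-sd
separation along the first axis) min-max scaled to `[0, 1]`. Passing tests
on these fixtures demonstrates that the optimizer and pipeline mechanics
work; they say nothing about screening accuracy on real compound
collections, whose headline numbers depend on undeposited compound lists.

## Problem sizes and determinism

Default training budgets (population 30, 10 GP generations, 20-iteration
screens, 100-iteration final run) fit the 120-sample fixtures in a few
seconds on one core; the acceptance-level 10-fold CV uses 5 GP
generations. All randomness flows from a single `numpy` generator per run,
so training, selection, fold assignment, and the CLI outputs are
deterministic given a seed.

## Known limitations

* Only the Gaussian activation and single-output trees are supported.
* No structural regularization beyond the depth bound; evolved trees can
  use a feature repeatedly.
* SSA position handling clamps to bounds; no reflection or re-sampling.
* The follower-update interpretation (midpoint) is documented above; the
  alternative literal reading (half-difference) is not implemented.
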