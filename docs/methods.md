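# Methods

## Model and assumptions

The unit of computation is a fixed-depth decision tree over a fixed feature
subset of size *n*, with one linear-threshold neuron per node and
coefficients restricted to a finite range, {−1, 0, +1} by default. The
model assumes a complete real-valued feature table and a binary outcome
with both classes present; there is no missing-data handling anywhere — a
combinatorial search over exact dichotomies has no sensible notion of
imputation, so incomplete input is a hard construction-time error.
Observations are never resampled or weighted: every tree is grown on all
samples once, so differences between trees come only from the random
feature subsets and the data itself.

### Node search

For a given coefficient vector, the achievable dichotomies of the active
sample set are exactly the cut positions between consecutive distinct
projection scores; the search therefore considers the midpoints between
consecutive distinct sorted scores plus one value below the minimum and
one above the maximum. This is finite and complete: no threshold outside
this set produces a dichotomy not already represented. Prediction uses a
strict inequality (score > threshold ⇒ positive); scores exactly on the
threshold predict negative. Both conventions are fixed choices made for
determinism where a convention was genuinely open.

A finalization step is admissible only when every finalized sample's
assigned label equals its true label; among admissible candidates the step
keeps the largest finalization, which is optimal: restricting a later
neuron sequence to a subset of samples preserves its admissibility, so
finalizing more samples never hurts. Ties among equally optimal coefficient
vectors break to the lexicographically smallest (−1 < 0 < +1), and the
optimal threshold for a chosen vector is unique given the maximal
finalization, so whole forests are reproducible bit for bit from the seed.

### Tree growth and termination

Steps alternate finalize-negative, finalize-positive (one cycle = one step
of each; the negative polarity leads, a fixed choice — the alternation
order is configurable). Before every step the grower checks whether any
vector classifies the entire active set without error; if so that neuron is
applied to both sides and the tree terminates perfect. Neurons that
finalize nothing still consume one of the (default six) steps: depth is a
fixed budget, not an adaptive quantity, and there is no pruning.
`verify_perfect` re-derives sensitivity and specificity purely from the
finalized assignments, independently of the growth path, and is asserted
for every perfect tree in the test suite.

### Solution counting

A node's solution count is the number of coefficient vectors attaining its
optimal finalization; thresholds form continuous intervals and are never
counted. When *every* enumerated vector attains the optimum (e.g. a pure
active set, or a step whose best finalization is empty) the node — and
hence the tree — is *unconstrained*, modelling the "infinite solutions"
case; otherwise the tree's multiplicity is the product of per-node counts,
and a product of 1 is a unique solution. NIC9 counts unique-or-finite
trees, NIC10 unique only.

One consequence of the deterministic tie-break is worth knowing: when a
perfect tree has several optimal vectors, the *reported* sign profile is
that of the lexicographically smallest one. With multi-feature neurons a
separable feature paired with noise typically admits optima with the noise
coefficient at −1, 0 and +1, so the reported profile is often non-monotone
and NIC6 rises even though a monotone solution exists. Single-feature
forests — the screening design — are unaffected, because multiplicity > 1
there only occurs in the unconstrained cases.

### Search modes

`EXHAUSTIVE_GREEDY` (default) enumerates all |range|^n vectors per node and
is exact per node, greedy across nodes. `FULL_ENUMERATION` additionally
falls back to a memoized depth-first search over every admissible
(vector, dichotomy) sequence when the greedy tree is imperfect; it is
exponential and intended as a correctness oracle at small n and sample
size — across thousands of random small instances in the tests the greedy
grower has never disagreed with it on perfect-tree existence.
`SAMPLED_HEURISTIC` replaces enumeration with a fixed-size pool of distinct
random vectors for large n (3¹⁵ ≈ 1.4 × 10⁷ vectors per node is out of
reach exhaustively); it is clearly non-exhaustive: perfection can be
missed, and solution counts are relative to the sampled pool.

## Forest parameters

- `n_features_per_neuron` (default 1): the screening design uses 1 —
  single-feature trees measure each feature's own potential; 2, 3 and 15
  are the confirmation designs (adjusted; or stratified with exactly one
  previously selected feature per tree).
- `min_instances_per_feature` (default 100): the stopping rule draws trees
  until every feature has been *selected* into at least this many trees —
  selection count, not perfect-tree count, which matches the per-feature
  tree counts the method reports. The published full-scale run implies a
  mean of 153 selections per probe at quota 100, consistent with the
  overshoot this stopping rule produces on large pools.
- `seed`: tree *i* draws from a generator keyed by (seed, *i*), so the plan
  and every tree are independent of worker scheduling; integer tallies are
  summed in tree order and parallel runs are bitwise equal to serial runs.
- `max_trees` (default 10 × quota × features) guards against an unreachable
  quota; hitting it is a warning, not an error.

## NICs, score and selection

NIC1 divides by the selection count; NIC2–NIC4 and NIC6–NIC10 divide by the
perfect-tree count; NIC5 = NIC3 × NIC4. A feature with no perfect trees has
all ratios set to 0 and a `no_pt` flag; such features rank last in both
rankings but are never dropped — absence of perfect trees is evidence
about the data, and the feature may still be an essential intermediate.
NIC5 and NIC7 are reported but excluded from the score (NIC5 has no defined
normalization onto [0, 1] as a score term and is reported raw; NIC7 is
nested in NIC8). Scores are computed at full precision and rounded to two
decimals only when printed; ranking ties resolve by input (feature) order
via stable sorts. The default hierarchical key order is
(1−NIC2)/NIC1/NIC10/NIC8; the alternative NIC1-first ordering is available
by passing a different key sequence. Gap selection sorts scores descending
and cuts at the first adjacent difference ≥ `min_gap` (default 1.0); if no
such gap exists the full list is returned flagged, rather than guessing a
cut.

## Synthetic data

The generator emulates the target input shape — continuous class-
conditional Gaussian features, a Bernoulli(prevalence) outcome, a feature
pool dominated by noise — with planted archetypes whose forest behaviour
is analytically predictable: SEPARABLE (shift Δ = 20 σ by default, giving
non-overlapping class ranges at n ≤ 200 with near certainty, hence
single-neuron perfect trees), MONOTONE_WEAK (Δ = 0.5 σ), PARADOXICAL
(class shift sign flips with an exposed Rademacher context feature),
INTERMEDIATE_NULL (deterministic average of two planted parents) and NOISE
(optionally Student-t with 3 df). It does **not** simulate array
normalization, batch effects, probe-level replicate correlation or
feature–feature correlation structure beyond the planted constructions, so
passing recovery tests demonstrates correctness of the machinery under
clean planted signal, not performance on real arrays; technical replicates
in real data are treated as independent samples.

## Benchmarking

The comparison protocol is stratified 3-fold cross-validation repeated 20
times, with identical folds for every feature set and classifier so that
differences are attributable to the selections. Classifier families:
quadratic-kernel SVM ((x·x′ + 1)², standardized inputs), logistic
regression (standardized, 2000 iterations) and a 200-tree random forest.
MCC and accuracy are computed from the confusion matrix with the
convention MCC = 0 when any margin is zero, and reported as mean ± sd over
the 60 fold evaluations. The stepwise curve fits maximum-likelihood
logistic models on the top-k ranked features with AIC = 2(k+1) − 2 log L
(intercept counted); fits that reach complete separation have no finite
optimum and are flagged, with the AIC reported at the iteration-capped
likelihood.

## Problem sizes in the tests

The suite exercises forests of roughly 5–6 thousand single-feature trees
(50 features, quota 100, 40 samples) for the recovery checks, 250 random
instances of ≤ 8 samples for the greedy-vs-exhaustive equivalence, and
smaller randomized forests for the invariant and determinism properties;
these sizes make every documented property observable while keeping the
full suite under a minute of forest time.

## Known limitations

- Binary outcomes only; no multiclass, regression, probabilistic output or
  pruning.
- No missing-data support, by construction.
- The exhaustive per-node search is exponential in features per neuron;
  n = 15 requires the sampled heuristic, which cannot promise the
  perfect-tree rates an exhaustive search would find.
- Sign-profile reporting (hence NIC3/NIC4/NIC6) is tie-break-dependent
  when a tree's solution is not unique (see above).
- Whether the neuron carries a learned bias rather than a data-driven
  split threshold is an open modelling question; the midpoint-threshold
  reading implemented here is the documented choice.
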