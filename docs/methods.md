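# Methods

## The optimizer

Chaos Game Optimization (CGO) is a population metaheuristic whose update
rule mimics the chaos game used to draw fractals: to draw a Sierpinski
triangle, one repeatedly jumps halfway from the current point toward a
randomly chosen triangle vertex, and the visited points converge onto the
attractor. CGO transplants this idea into a search box `[L, U]^dim`. The
population holds `D` candidate solutions ("seeds"). For every seed `S_k`,
one iteration forms a *temporary triangle* from three vertices: `S_k`
itself, the global best solution `G`, and the centroid `M_k` of a randomly
chosen subgroup of the population. Four candidate points are generated
from the triangle:

    P1 = S_k + α (β G   − γ M_k)
    P2 = G   + α (β S_k − γ M_k)
    P3 = M_k + α (β S_k − γ G)
    P4 = S_k with uniform(0,1) additions on a random subset of coordinates

`β` and `γ` are random integers playing the role of die faces; `α` limits
the seed's mobility and is drawn from one of four formulas — `R`, `2R`,
`εR + 1`, `εR + ε` with `R, ε ~ U(0,1)` — the formula itself chosen
uniformly, which mixes small exploitation steps with occasional jumps
past the far vertex. All candidates are clipped into the box, evaluated,
and pooled with the incumbents; the best `D` by fitness survive
(minimization convention: "best" is lowest). Termination is a fixed
iteration budget only.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `population_size` (D) | 50 | seeds kept alive; the standard setting for the feature-selection experiments |
| `max_iterations` | task-specific | only stopping rule; 4·D objective calls per iteration |
| `beta_gamma_domain` | {1, 2} | die-face factors; {0, 1} selectable |
| `mean_group_size` | random in {1..D} | subgroup averaged into `M_k` |
| `alpha_per_dimension` | False | scalar α per candidate point; vector mode optional |
| `lower_bound`/`upper_bound` | 0 / 1 | box constraints (fixed to [0,1] for feature selection) |

Design choices that the published description leaves open, resolved here:

- **β/γ domain.** The textual description suggests {0, 1}; the parameter
  table for the same method lists (1, 2). The default is {1, 2}: with
  {0, 1} the bracketed difference frequently zeroes a vertex and the
  triangle geometry collapses. {0, 1} remains available.
- **ε** is a uniform real on (0, 1); the only reading that keeps the four
  α formulas distinct.
- **P4 mutation scope.** Each coordinate is included in the perturbed
  subset independently with probability `1/dim`, redrawn while empty, and
  each included coordinate receives an independent uniform(0, 1) addition
  before clipping. This guarantees `P4 ≠ S_k` while keeping the move local.
- **Replacement** is pool-and-truncate (D incumbents + 4D candidates →
  best D), an elitist population-level realization of "replace if
  better". Ties are broken toward earlier pool entries (incumbents first,
  then lower row index), making replacement deterministic.
- **Boundary handling** is clipping; reflection is not implemented.
- **RNG discipline.** One seeded generator per `optimize` call; draws
  happen in a fixed documented order (per seed: subgroup, then per
  candidate point α-formula index, R, ε, β, γ; then the P4 subset and
  additions). Equal seeds therefore give bitwise-equal traces.

### Behaviour on piecewise-constant objectives

Binarized objectives (below) are constant on the pre-image of each mask,
so almost every candidate move is a plateau move and elitist replacement
accepts only strict improvements. The population then collapses onto a
single mask well before the evaluation budget is spent; on structureless
(random lookup) objectives this caps the number of distinct masks a run
visits at roughly a tenth of its evaluations. Agreement with exhaustive
enumeration is therefore reliable for subset spaces up to ~2^6 at modest
budgets but degrades for larger spaces regardless of budget. On real
feature-selection objectives — where classifier error is far from
structureless — the collapse is benign: the population converges onto the
informative subset (see the planted-recovery results).

## Binary wrapper feature selection

A continuous seed `X ∈ [0, 1]^Dim` is thresholded into a Boolean mask
`BX`: bit j is 1 iff `X_j > 0.5`, strictly, so 0.5 itself maps to 0. The
mask is scored by the composite fitness

    Fit(BX) = λ · γ(BX) + (1 − λ) · |BX| / Dim

where `γ` is the classification error of a classifier trained on the
selected columns and `|BX|/Dim` the selected-feature ratio. Defaults:

- **λ = 0.99.** Unstated in the original description; the standard
  wrapper-FS convention is used — error dominates, subset size breaks
  ties between equal-error subsets.
- **γ protocol:** stratified 5-fold cross-validation on the *training*
  partition with a fixed shuffle seed, making fitness a pure
  deterministic function of the mask. One stratified split would be
  cheaper but noisier; fold count must not exceed the smallest class
  count.
- **Search classifier:** a linear support-vector machine (`svm`), the
  stability-motivated choice; `knn` (5 neighbours) and `sgd` (hinge-loss
  linear model, fixed seed and iteration cap) are available because final
  reporting pairs the selector with each of the three.
- **Empty mask:** fitness 1.0 — the worst achievable value — assigned
  without calling a classifier, keeping the objective total and finite.
- **Final protocol:** after the search, the chosen final classifier
  (default `sgd`) is refit on the full training partition restricted to
  the selected columns and evaluated exactly once on the held-out test
  partition.
- **Caching:** because fitness depends on the seed only through its mask,
  evaluations are memoized per mask within a run. This changes no result;
  it cuts classifier fits roughly tenfold at the default budgets.
- **Data hygiene:** `select_features` copies the training rows out of the
  table before the search begins; test rows are physically absent from
  every fitness evaluation.

## Metrics and method comparison

Binary tasks report recall, precision, accuracy, F1, sensitivity,
specificity and balanced accuracy from the positive class's confusion
counts (`recall = TP/(TP+FN)`, `specificity = TN/(FP+TN)`,
`balanced accuracy = (sensitivity + specificity)/2`, and so on).
Multiclass tasks use one-vs-rest counts per class, combined
support-weighted by default (macro available); weighted averaging makes
reported recall numerically equal accuracy, which is the convention the
final-report layout assumes. Balanced accuracy is always the unweighted
mean over classes of the per-class `(sensitivity + specificity)/2`.
A class with no predicted positives gets precision 0 with a logged
warning rather than a hole in the report.

Methods are compared with the Friedman test: within each dataset the
methods are ranked (rank 1 = best, ties share the average rank); mean
ranks are averaged across datasets, and the tie-corrected chi-square
statistic with its p-value accompanies them. The statistic is computed
in-package from the textbook formula and is cross-checked against an
independent implementation in the test suite. No post-hoc tests are
performed.

## Synthetic data generator

The generator emulates fixed-length image-embedding tables (default 128
columns) with known ground truth:

- **informative** columns: standard normal noise plus a per-class mean
  shift of `class_separation × class_index` (separation 1.0 default — a
  1σ shift per class step, a moderately hard problem for ~100 samples
  per class);
- **redundant** columns: `ρ·source + sqrt(1−ρ²)·noise` against an
  informative source column (including its class shift);
- the remaining columns: pure standard normal.

The split is stratified so every class appears in both partitions, and
identical spec + seed reproduce the table bitwise. The Gaussian
class-shift model was chosen for analytical tractability of the planted
separation; it does not emulate heavy tails, feature-scale heterogeneity,
label noise, or the correlated activation patterns of real CNN
embeddings. Passing the planted-recovery experiments therefore shows the
selector finds linearly separable signal among Gaussian noise — not that
it matches any particular accuracy on real images.

## Problem sizes used in the shipped experiments

- Continuous convergence: 2-D sphere, D = 20, 200 iterations, 20 seeds.
- Exhaustive-oracle agreement: 6-bit lookup objectives, D = 64,
  12 iterations (3 136 candidate evaluations against 63 enumerable
  non-empty masks), 20 seeds.
- Planted recovery: Dim = 32 with 5 informative columns, 100 samples per
  class, D = 30, 60 iterations, λ = 0.99, 20 seeds.
- Benchmark demo: CGO vs budget-matched random search, three synthetic
  datasets, D = 20, 30 iterations.
- Chaos-game demo: 10^5 points, box counting at dyadic levels 2^2..2^7.

## Known limitations

- Only box constraints; no constraint handling, no parallel evaluation,
  no stagnation-based early stopping.
- The eight comparison metaheuristics of the original study are not
  implemented; the pluggable optimizer interface and the random-search
  baseline stand in for them.
- Binarization by fixed 0.5 threshold (no transfer functions); plateau
  collapse on structureless objectives as described above.
- The generator's Gaussian model understates the difficulty of real
  embedding tables.
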