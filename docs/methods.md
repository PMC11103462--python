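# Methods

This note records the scientific choices behind `optforest`: the model, the
defaults and why they are what they are, the conventions adopted where the
underlying procedure is ambiguous, and what the synthetic experiments do and
do not demonstrate.

## Problem setting

The target data shape is a pre-extracted biomedical feature table: a few
hundred records, a few hundred numeric descriptors (the motivating case is a
452-record, 279-feature ECG arrhythmia table), a nominal class column with a
long-tailed 16-class vocabulary in which several classes have a handful of
rows and some have none, and sporadically missing cells. Two difficulties
dominate: feature redundancy (many waveform descriptors are near-duplicates)
and ensemble overfitting (a full bagged forest carries many low-quality
trees whose votes dilute the good ones). The package addresses the first
with filter-style consensus feature selection and the second with
GA-driven subforest selection.

## Imputation

Missing feature cells are replaced by the per-feature mean of the observed
entries (μ_f), fitted once and applied to any table with the same columns.
A feature with no observed values cannot be imputed and raises an error
naming the feature. Rows with a missing *class* label are dropped with a
warning: imputing a label would fabricate training signal. A mode-imputation
strategy exists for 0/1-coded descriptors but is off by default, since the
target tables are treated as all-numeric.

## Feature-selection objective

Both objectives are built from the same two merit components, computed once
per table so that the three searches optimize an identical function:

- IP(i): the correlation ratio η of feature i against the class — the
  square root of the between-class share of its variance. η handles a
  many-class nominal target with numeric features, is scale-free, and is 0
  for a constant feature. A symmetric-uncertainty estimator (after
  equal-width 10-bin discretization) is available as an alternative.
- R(i, j): the absolute Pearson correlation between feature columns, with
  the convention that a constant column correlates 0 with everything.

With TP(S) = Σ IP and TR(S) the double sum of R over *ordered* pairs (each
unordered pair counted twice — a halved convention would rescale TR without
changing the ranking of equal-sized subsets):

**Consistency score** — TP/(TP + TR), with empty sets and TP = TR = 0
scoring 0. This score is degenerate: every singleton with IP > 0 scores
exactly 1, and any multi-feature subset with nonzero sample correlations
scores strictly less, so a search maximizing it literally collapses to a
single feature. We therefore impose a total tie-break order — score, then
larger TP, then smaller |S|, then lexicographic feature order — which at
least makes the maximizer well-defined (the highest-IP singleton).

**CFS merit** — TP/√(|S| + TR), the classical correlation-based
feature-selection criterion. This is the objective that CFS-style attribute
evaluators actually maximize in practice, and unlike the consistency score
it *grows* as relevant, mutually uncorrelated features are added, so its
optimum is a genuinely multivariate subset. The low-level search functions
default to the consistency score (the score the original procedure
describes); the selector estimators and the pipeline default to the CFS
merit, because a selection front end that can only ever return one feature
is not usable. Both objectives are one keyword apart everywhere.

## Search strategies

All three searches share the tie-break order above and are deterministic
given their seed.

- **Harmony Search** (memory 20, HMCR 0.9, PAR 0.3, 200 iterations): one
  candidate mask per iteration, each bit copied from a random memory member
  with probability HMCR (else random), then flipped with probability PAR;
  the candidate replaces the worst memory member when it scores higher.
  The PAR flip applies to the chosen bit whether it came from memory or not.
- **Best-First** (stale limit 5): deterministic bidirectional hill climb
  from the empty set; at each step the best not-yet-visited single-bit
  neighbour becomes current, and the search stops after five consecutive
  expansions that fail to improve the best subset seen. The visited-set
  memory prevents cycling between a subset and its complement move.
- **Binary PSO** (swarm 20, w 0.72, c₁ = c₂ = 1.49, v_max 4, 100
  iterations): canonical velocity update on 0/1 encodings with fresh random
  coefficients per component, clipped to ±v_max; positions are re-binarized
  through a sigmoid transfer (bit ← 1 iff U(0,1) < 1/(1+e^(−v))), the
  standard discretization when the position update is written for continuous
  coordinates. Velocities start at zero; inertia w ≈ 0.72 with c ≈ 1.49 is
  the constriction-style parameterization.

The HS/BPSO hyperparameters follow common metaheuristic practice; only the
PSO velocity coefficients are inherited from the procedure itself. The
**majority vote** then keeps the features present in at least two of the
three subsets. Applied to the three published arrhythmia search subsets
(22, 25 and 37 features), the vote yields **17** features — the 16 printed
as the consensus row plus `t_interval`, which appears in both the
Best-First and PSO rows. The printed 16-feature row is internally
inconsistent with the vote rule it accompanies; the implementation follows
the rule and the worked-example test asserts 17.

## Forest and tree quality

Induction is bagging with random-subspace CART: each of T = 100 trees is
trained on a bootstrap resample (indices recorded) with √F candidate
features per split, Gini impurity, unlimited depth. Per-tree quality is
accuracy on the tree's out-of-bag rows — an unbiased private validation set
that leaves the GA's fitness fold untouched; a tree with no OOB rows
(vanishingly rare at n ≥ 30) falls back to training accuracy and is
flagged. Trees are ranked by quality into three strata of near-equal size
(34/33/33 for T = 100, configurable), ties broken by tree index.

## Genetic algorithm

Fitness is the ensemble accuracy EA of the masked subforest's soft vote
(mean of per-tree class-score vectors; argmax with ties resolved in
vocabulary order) on an internal validation fold — by default a stratified
20 % of the training split. Using training accuracy would reward
overfitting; using the test set would leak it.

Per run, with |P| = 20, M = ⌈T/5⌉ trees per initial chromosome, J = 30
iterations:

1. **Seeding** (once): ten chromosomes by disproportionate stratified
   sampling — round(0.6 M) trees from S1, round(0.3 M) from S2, remainder
   from S3, without replacement within a stratum and with overflow spilling
   to the next stratum — and ten uniform. Re-randomizing the population
   every iteration would discard all evolution, so seeding runs once; a
   literal re-seed-per-iteration mode exists for fidelity experiments.
2. **Crossover/mutation**: ten parent pairs by roulette (p ∝ EA, uniform
   when all EA = 0; the two parents of a pair distinct), one-point
   crossover at a uniform interior cut, then exactly one uniformly chosen
   bit flipped per offspring.
3. **Elitism**: the offspring best is promoted to the so-far best on strict
   improvement; the parent best replaces the worst offspring on strict
   improvement. Ties always preserve incumbents, which keeps runs stable.
4. **Survivor selection**: 20 survivors drawn by roulette *without*
   replacement from the pooled 40, preserving diversity.
5. **SSO rectification** of the so-far best, each iteration: one ascending
   pass flipping set bits 1→0, then one pass 0→1, keeping only strictly
   EA-improving flips and never emptying the mask.

Chromosome cardinality may drift from M after crossover, mutation and SSO;
M is a seeding parameter, not a constraint. Each stochastic component
(seeding, parent selection + crossover, survivor selection) draws from its
own stream spawned from the master seed, so toggling one feature does not
shift another's draws. EA of the so-far best is non-decreasing by
construction and never below the best initial chromosome.

## Evaluation metrics

One-vs-rest reductions of the C×C confusion matrix (zero-count classes keep
their row and column, so the arrhythmia matrix is always 16×16). TPR_c =
TP/(TP+FN), defined as 0 for a class with no true rows; CA = trace/N;
κ = (P_o − P_e)/(1 − P_e); single-number TPR/FPR are prevalence-weighted
means (weighted TPR is then identically CA — asserted in tests). Two FPR
conventions exist: the standard FP/(FP+TN) (default) and the literal
FP/(FP+FN) printed in the source procedure, which is insensitive to true
negatives and contradicts the name; it is kept behind `paper_literal_fpr`
for reproduction studies only. RMSE is computed on class-probability
vectors against one-hot truth, normalized by N·C, which keeps it in [0, 1];
the scalar formula requires some convention for vector-valued predictions
and this is the one adopted. ROC areas use trapezoidal integration with
tied scores grouped; PRC areas use the average-precision step rule; classes
without both a positive and a negative row are reported NaN and excluded
from the renormalized weighted averages.

## Synthetic fixture

The generator emulates the study table's *shape*: exact per-class counts
(452 rows, 16 classes, three empty), 279 features, i.i.d. standard-normal
noise features, planted informative features whose per-class means are
drawn N(0, Δ²) with Δ = 1.5 sd (10 planted by default, evenly spread over
the columns), 20 redundant pairs built as ρ·source + √(1−ρ²)·noise with
ρ = 0.95 from non-planted columns, and 2 % uniformly missing cells. It does
**not** emulate real ECG descriptor distributions — skewness, heavy tails,
block-correlation structure among related waveform measurements, or
label-dependent missingness. Passing tests therefore demonstrate that the
algorithms are implemented correctly and behave sensibly under a controlled
signal model, not that any particular accuracy will transfer to clinical
tables.

## Problem sizes used in the checks

The acceptance checks run at deliberately compact sizes chosen as the
smallest that exercise each property: search-vs-oracle on 25 merit tables
of ≤ 12 features (exhaustive enumeration stays cheap), GA invariants and
effectiveness on a separable two-blob set (n = 400, T = 30, 20 seeds),
toy-scale GA optimality on stub forests of T = 10 fixed vote tables against
full enumeration of all 1023 masks, and planted-feature recovery on the
default 452×279 fixture over 10 seeds. The full pipeline itself runs at the
study scale (T = 100, J = 30, 279 features) in about a second.

## Known limitations

- On a cleanly separable fixture the full forest, the GA subforest, and a
  random subforest all reach EA = 1.0, so the GA-versus-random comparison
  there verifies "never worse", not a strict improvement; the GA's value
  shows on noisier data where low-quality trees actively hurt the vote.
- The consistency score is kept verbatim for fidelity but is not a usable
  selection objective (see above); results obtained with it reduce to
  single-feature selection by construction.
- Harmony Search evaluates one candidate per iteration (200 total by
  default), far fewer than PSO's 2000; its subsets are correspondingly
  closer to its random initialization on large tables.
- Imputation and feature selection run on the full table before the
  train/test split, mirroring the original experimental procedure; this
  leaks marginal feature statistics across the split and slightly flatters
  test metrics compared to a fully nested protocol.
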