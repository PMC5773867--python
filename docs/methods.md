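# Methods

This note documents the models, numerical choices and limitations behind
casgrn, in the spirit of a statistical package's methods appendix. It
describes what the code computes; every number quoted here is recomputed by
the test suite or by `scripts/acceptance.py`, not asserted from memory.

## 1. Mutual-information estimation

MI is estimated by the plug-in identity MI(X, Y) = H(X) + H(Y) − H(X, Y)
with maximum-likelihood (empirical-frequency) entropies in natural log
units (nats). Two deliberate choices:

* **No small-sample bias correction** (no Miller–Madow, no shrinkage). The
  breakpoint model below explicitly treats the positive bias of plug-in MI
  between independent variables as its null "noise" population; correcting
  the bias would remove the very signal the breakpoint detector separates.
* **Nats, not bits.** The breakpoint statistic is invariant to a global
  rescaling of the MI vector when no variance floor binds (a log-base
  change is such a rescaling), so the base is cosmetic; nats keep the
  Gaussian likelihood formulas clean. The CLI offers a bits display flag.

Floating-point residue is clamped: pairwise MI is forced into
[0, min(H(X), H(Y))] so the ranking never carries a negative entry.

## 2. Breakpoint detection and candidate selection

For each target, the n−1 pairwise MIs are sorted ascending and modeled as
two Gaussian populations — unrelated-gene noise on the left, related genes
on the right — separated by a single breakpoint k. The statistic is twice
the log-likelihood ratio of the two-segment maximum-likelihood fit against
the pooled single-Gaussian fit, maximized over k. Candidates are the genes
ranked strictly above the argmax.

Numerical and boundary conventions:

* **Variance floor.** Every fitted segment standard deviation is floored
  at σ_floor = 1e-4 nats. This keeps single-point and constant segments at
  finite likelihood and makes Q on an exactly constant vector identically
  zero. Because each segment's constrained optimum (variance ≥ floor) still
  dominates the pooled constrained optimum, Q ≥ 0 holds exactly, floor or
  not.
* **Split range k ∈ [1, m−1].** A split at k = m would leave an empty
  right segment, so the last position is excluded; single-point segments
  are admissible because the floor handles their degenerate variance. This
  matters in small panels: with four variables each ranking has m = 3
  entries, and requiring two points per segment would make pruning
  impossible exactly where the common-effect demonstration lives.
  Rankings with m < 3 return a keep-all result.
* **Significance gate.** There is no tuned threshold. A numerical epsilon
  (1e-9) distinguishes the exact-null case (all values equal) from a real
  maximum; when nothing exceeds it, all genes are kept — the restriction is
  an optimization, so the safe degenerate behavior is no restriction.
* **Ties.** Equal Q resolves to the smallest k, i.e. the larger candidate
  set. For a search-space restriction, wrongly excluding a true neighbor is
  the unrecoverable error; wrongly keeping a non-neighbor only costs
  search time.
* **Implementation.** Q(k) for all k is computed in one prefix-sum pass
  over the mean-centered vector; because cancellation in power sums can
  leave ~1e-6 noise on near-degenerate segments, the near-argmax region is
  re-scored with the exact two-pass likelihood, so the reported (k, Q)
  match a brute-force evaluation to machine precision.

## 3. BDeu scoring

Families are scored with the Bayesian Dirichlet equivalent uniform
marginal likelihood with equivalent sample size ess (default 1, the common
convention; exposed everywhere). Parent configurations never observed
contribute exactly zero and are skipped, which keeps large candidate sets
affordable. Scores are cached keyed on (child, parent set); the cache is
bit-transparent. No maximum-parents cap is imposed by default — the
candidate sets are the only restriction — though a safety flag exists.

## 4. Structure search

All searches start from the empty graph and use add-only moves: each
iteration adds the single highest-gain edge whose gain is strictly
positive and which does not create a cycle, and stops when none remains.
Ties break lexicographically, so runs are deterministic. Delete/reverse
moves exist behind a flag but are off by default.

* **Benchmark greedy** searches the full n(n−1) edge space.
* **CAS+G** searches the union space {(u,v) : u ∈ C(v) or v ∈ C(u)}. The
  OR-union is the recall-preserving reading of per-node candidate sets:
  an edge is admissible if either endpoint nominated the other.
* **CAS+L** runs one greedy search per node v over
  E(v) = {(v,u), (u,v) : u ∈ C(v)}, records each accepted edge with its
  acceptance-time gain, pools all edges (duplicates keep the larger gain),
  and merges them in descending-gain order, skipping edges that close a
  cycle or reverse an already-accepted edge. The per-node searches are
  independent, so node order cannot change the result; since every local
  search starts from the empty graph, the initial gain table is computed
  once and shared.
* **Exhaustive enumeration** of all labeled DAGs is available up to four
  variables as an exact-optimum oracle (25 DAGs at n=3, 543 at n=4).

Known limitation: the first edge a greedy search adds is orientation-tied
exactly (BDeu scores Markov-equivalent one-edge graphs identically), so
its direction is an arbitrary lexicographic pick. When the true graph is a
pure collider, a misoriented first edge cannot be repaired by add-only
moves and the search ends in an over-connected local optimum; this accounts
for essentially all of the ~7% of sparse 3-node instances where CAS+G
misses the enumeration optimum.

## 5. Evaluation

Structure recovery is scored as a binary classification over the full pair
universe — ordered pairs in directed mode, unordered in skeleton mode —
with precision, recall, accuracy, specificity, F-score, and structural
Hamming distance (reversal cost 1). On sparse graphs accuracy and
specificity are dominated by true negatives; they are reported as defined.
Candidate sets are scored by mean per-node recall against the true
undirected neighborhood, plus mean candidate count.

When comparing CAS+L against CAS+G, quality is compared on **skeletons**:
a large share of orientations is not identifiable from observational data
(score-equivalent ties), and the local learner's orientation of its first
star edge is a pure tie-break convention, so directed F-score would charge
it for noise no observational method can resolve. Directed metrics remain
the default everywhere else and the CLI prints both modes.

## 6. Synthetic data generator

The generator emulates the benchmark setting the method targets: sparse
expert-network-like DAGs and i.i.d. ancestral samples.

* `random_dag(n, mean_degree, max_indegree, seed)` draws edges
  independently from lower to higher position in a random topological
  order (edge probability mean_degree/(n−1)), caps indegree, and shuffles
  labels. Defaults used in tests: 30–50 nodes, mean degree 2.5, max
  indegree 4 — the sparsity regime of curated benchmark networks and
  DREAM-scale in-silico GRNs.
* `random_cpts(dag, cardinality=3, concentration=0.5, seed)` draws every
  CPT row from a symmetric Dirichlet. Concentration 0.5 gives peaked,
  learnable dependencies ("strong CPTs"); cardinality 3 matches the
  three-level discretization default.
* `forward_sample` performs ancestral sampling; sample sizes in tests span
  50–5000, covering the span from scarce to comfortable.
* `collider_fixture()` is the fixed 4-node network X → Z ← Y, Z → W with
  a near-OR gate at Z (5% flip noise) and a noisy copy at W — strong
  enough that 5000 samples separate signal MI (~0.1–0.3 nats) from
  independence noise (~1e-4 nats) decisively.
* `planted_breakpoint_vector` builds sorted vectors of two clamped
  Gaussian populations with a known separator for direct breakpoint
  benchmarks; the canonical setting (m=50, split 40, N(0.01, 0.005²) vs
  N(0.5, 0.05²)) has negligible overlap, so the planted separator is
  well defined.

What the generator does **not** emulate: expression kinetics (no ODE or
measurement-noise simulation), hub-heavy degree distributions, hidden
confounders, interventional data, or non-i.i.d. samples. Passing tests
demonstrate correct behavior of the algorithms under their own model
assumptions at benchmark scale, not performance on any real expression
compendium.

## 7. Discretization

Continuous expression is binned per gene by 1-D k-means (default 3
levels): centroids initialize at the (i+0.5)/k quantiles and plain Lloyd
iterations follow, so the procedure is deterministic and
sample-order-independent; categories are relabeled by ascending centroid,
making index 0 always the lowest-expression bin. Genes with fewer distinct
values than levels keep one category per value; constant genes collapse to
a single category with a warning. Missing values are rejected by default.

## 8. Problem sizes and determinism

Every stochastic routine takes an explicit seed and threads it through a
dedicated generator; no global random state is used or mutated. The test
and reproduction-script problem sizes (up to 50 nodes, 1000–5000 samples,
20–300 seeded replicates per property) were chosen so the entire suite
runs in well under a minute per property on a single CPU while keeping
binomial noise on rate estimates small relative to the margins being
checked; the one property measured over 300 replicates (agreement with
exhaustive enumeration) is the one whose true rate sits closest to the
margin its test checks.
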