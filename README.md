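# casgrn

Bayesian-network structure learning for gene regulatory network (GRN)
inference from discrete expression data, built around **candidate
auto-selection (CAS)**: a parameter-free screening step that decides, for
every gene, which other genes are worth considering as neighbors before any
score-based search begins.

## The method

Score-and-search structure learning scales badly because the search space
over directed acyclic graphs is super-exponential. Constraint-based
screeners (MMPC-style) prune it but need significance thresholds and large
samples. CAS instead exploits a distributional signature:

1. For a target gene *g*, compute the mutual information
   MI(X, Y) = H(X) + H(Y) − H(X, Y) against every other gene and sort the
   resulting vector 𝒳 = (x′₁ ≤ … ≤ x′ₘ), m = n − 1, ascending.
2. Unrelated genes (including marginally independent co-parents in a
   common-effect configuration X → Z ← Y) contribute only small-sample MI
   noise; related genes contribute genuinely positive MI. Model each group
   as its own Gaussian and test for a single breakpoint *k* by the
   likelihood-ratio statistic

   Q(k) = 2 [ L(x′₁…x′ₖ; θ̂₁) + L(x′ₖ₊₁…x′ₘ; θ̂₂) − L(x′₁…x′ₘ; θ̂) ],

   with each θ̂ = (μ̂, σ̂) the Gaussian maximum-likelihood fit of its
   segment. The breakpoint is k* = argmax Q(k); genes ranked above it form
   the candidate set C(g). No tuning threshold is involved.
3. Learn the network by greedy BDeu hill climbing restricted to candidate
   edges — either globally (**CAS+G**) or per node with a cycle-free merge
   of the local structures (**CAS+L**, faster, nearly as accurate on
   adjacency recovery).

Families are scored with the BDeu marginal likelihood
Σⱼ [ lnΓ(αⱼ) − lnΓ(αⱼ+Nⱼ) + Σₖ ( lnΓ(αⱼₖ+Nⱼₖ) − lnΓ(αⱼₖ) ) ],
αⱼₖ = ess/(r·q), so Markov-equivalent DAGs score identically.

## Worked example

Four genes with ground truth X → Z ← Y, Z → W (the common-effect
configuration that defeats plain pairwise-MI screening):

```python
import casgrn as c

bn = c.collider_fixture()                      # known ground truth
data = c.forward_sample(bn, 5000, seed=11)     # 5000 sampled records

sel = c.CandidateSelection(data).fit()
print(sel.summary())
#       n_candidates  breakpoint_k          Q  significant   left_mu  right_mu
# node
# W                1             2  34.689541         True  0.084242  0.310998
# X                2             1  16.484311         True  0.000168  0.112710
# Y                2             1  16.404345         True  0.000168  0.116999
# Z                1             2  26.717206         True  0.145467  0.310998

res = c.StructureLearner(data, method="casg").fit()
print(sorted(res.graph.edges()))
# [('W', 'Z'), ('Z', 'X'), ('Z', 'Y')]
print(res.evaluate(bn.dag, mode="skeleton"))
# {'precision': 1.0, 'recall': 1.0, 'accuracy': 1.0, 'specificity': 1.0,
#  'f_score': 1.0, 'shd': 3}
```

Reading the output: X's sorted MI vector breaks after position 1 — the
near-zero MI against its co-parent Y (left segment mean ≈ 0.0002 nats) is
cut off, while Z and W (right segment mean ≈ 0.11 nats) survive as
candidates. The learned graph recovers the true skeleton exactly
(skeleton F-score 1.0); the three reported SHD edits are orientation
reversals, which BDeu cannot resolve from observational data because both
orientations of those edges score identically.

## Command line

Every stage is also a `casgrn` subcommand, each writing a JSON sidecar
with the resolved configuration and seed:

```sh
casgrn simulate --nodes 30 --samples 210 --seed 1 --out-prefix sim
casgrn candidates sim.data.tsv --out cands.tsv --diagnostics qprofile.tsv
casgrn learn sim.data.tsv --method casl --out learned.tsv --summary run.json
casgrn evaluate sim.gold.tsv learned.tsv
```

Continuous expression matrices are binned first with
`casgrn discretize --levels 3` (per-gene k-means, centroid-ordered
categories). Benchmark networks in BIF format are read with
`casgrn.read_bif`; gold standards use DREAM-style
`regulator<TAB>target<TAB>{0,1}` edge lists.

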