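# Methods

## Model

The interactome is an undirected simple graph over opaque gene identifiers;
self-loops and duplicate edges are removed at load time and nodes are
ordered lexicographically, fixing the coordinate system of every vector.
The transition matrix `M` is the column-normalized adjacency: column `j`
spreads a walker at gene `j` uniformly over its neighbors.  The random walk
with restart

    P_{t+1} = (1 − γ) M P_t + γ P0

has a unique stationary distribution for γ ∈ (0, 1] (the map is a
contraction with L1 rate 1 − γ); it equals the resolvent
`γ (I − (1 − γ) M)⁻¹ P0` whenever every column of `M` is stochastic.  The
stationary vector — the diffusion profile — summarizes the start
distribution's position in the whole network: γ near 1 keeps the mass local,
γ near 0 approaches a global, degree-driven view.

A disease profile starts from the phenotype-weighted vector
`D̃0 = D0 + λ Σᵢ δ(d,dᵢ) Sim(d,dᵢ) D0ⁱ`.  Two modeling choices here were
genuinely open and are resolved as follows:

* **Self-term.**  The sum excludes `dᵢ = d` itself.  Including it would only
  rescale `D0` by a constant, which the scale invariance of the downstream
  scores makes irrelevant, but exclusion matches the reading that only
  *other* diseases contribute.
* **Normalization.**  `D̃0` as written does not sum to 1; we renormalize it.
  Both the Pearson correlation and the cosine are invariant to positive
  rescaling of either argument, so renormalization provably changes no
  DP_LCC/DP_COS ranking (a property test verifies this against an
  unnormalized resolvent solve); it simply preserves the probabilistic
  reading of the walk.  For the component-score baselines the normalized
  start is the defined behavior.

Candidates are ranked by descending score.  Ties all receive the *worst*
rank of their tie group, so an uninformative scorer is never credited by the
evaluation; undefined scores (a constant profile under the correlation, an
all-zero vector under the cosine — possible only on degenerate networks)
rank last.  Tie-break for presentation order is lexicographic gene id.

## Parameters

| parameter | default | meaning |
|---|---|---|
| γ (`gamma`) | 0.25 | restart probability; locality/globality trade-off |
| λ (`lam`) | 0.5 | weight of similar diseases' start vectors |
| similarity threshold | 0.3 | below this, phenotype similarity carries no signal |
| `tol` | 1e-6 | L1 convergence threshold of the iteration |
| `max_iter` | 10 000 | safety bound; convergence is geometric at rate 1 − γ |
| `n_controls` | 99 | control genes per leave-one-out case (candidate sets of 100) |
| rank-ratio step | 0.01 | ROC threshold grid |
| PRINCE `c`, `d` | −15, log 9999 | logistic prior parameters |

γ = 0.25 and λ = 0.5 are the grid-search optimum of the method's top-1
precision on its original benchmark; the 0.3 threshold is the established
informativeness cutoff for MimMiner-style similarities.  Ranking quality is
fairly flat in γ, which the `sweep` command lets users confirm.

## Numerical choices

* **Isolated nodes** have all-zero transition columns, through which the
  iteration would leak probability.  Each iterate is renormalized to mass 1
  (a strict no-op when no mass sits on an isolated node); convergence is
  measured as the L1 distance between the raw update and the previous
  (renormalized) iterate.  The closed-form resolvent solve renormalizes once
  at the end, so on start vectors carrying isolated-node mass the two
  solvers can differ; on networks without isolated nodes, or indicator
  starts at connected genes, they agree to solver precision.
* **Convergence flagging.**  Hitting `max_iter` returns the last iterate
  flagged `converged=False` with a warning rather than raising.
* **Batched profiles.**  All-gene profiles iterate blocks of identity
  columns jointly (block size 512) with per-column convergence tracking;
  results are bit-identical to single-start runs.  The profile cache stores
  the matrix plus a JSON sidecar with γ, tol and a node-order hash, and
  refuses to load against a different node order.
* **ROC grid.**  Thresholds are `k·0.01`; comparisons use a 1e-12 slack so
  rank ratios that fall exactly on a grid point count on the intended side.
  AUC is trapezoidal over (1 − specificity, sensitivity) with (0,0) and
  (1,1) appended.  On shared data this reproduces the Mann–Whitney AUC.
* **Degenerate inputs.**  Empty networks, zero/negative start vectors,
  out-of-range similarities, contradictory duplicate similarity entries,
  reversed BED intervals and duplicate position records are all rejected
  with errors naming the offending file line where applicable.

## Cross-validation protocol

During leave-one-out the association is removed, not the gene: the held-out
gene stays in the network and in the candidate set.  By default the held-out
gene may still appear in *similar* diseases' start vectors when it also
causes them — the literal training-data construction; `strict_holdout=True`
removes it from every contributing disease for leakage analysis.  Random
controls exclude the test gene and (by default, switchable) the disease's
remaining training genes, which cannot meaningfully serve as negatives.
Control draws derive from `(seed, case-index)`, so runs are reproducible and
order-independent.  Artificial-linkage-interval controls are the `n`
same-chromosome genes nearest by interval midpoint (ties by gene id); a
chromosome with too few genes is topped up by random fill — this fallback is
an artifact of small synthetic genomes and is logged whenever used.  Cases
whose test gene lacks a position record are skipped and counted.

## What the synthetic generator does and does not emulate

The generator plants the two regularities the method exploits: disease
modules (gene sets grown in breadth-first neighborhoods, densified by
`module_cohesion`) and phenotype clusters whose member diseases draw genes
from a shared neighborhood pool, with within-cluster similarities drawn from
an informative range (default U(0.5, 0.9), above the 0.3 cutoff) and
cross-cluster ones below it (U(0, 0.2)).  The default bundle — 300 genes,
preferential-attachment topology with mean degree ≈ 8 (the density regime of
curated human PPI networks), 20 diseases of 2–4 genes — is sized for
seconds-scale leave-one-out runs while leaving ~60 evaluable cases.
`localized_modules=False` together with `module_cohesion=0` and overlapping
similarity ranges is the explicit null switch: disease genes are then
uniform random draws and every method should (and, in tests, does) perform
at chance.

What it does *not* emulate: the true interactome's size, its ascertainment
biases (study-frequency correlates of disease genes), hub-disease
correlations, incomplete and false-positive interactions, or realistic
genome geography (positions are evenly spaced with jitter on a few synthetic
chromosomes).  Passing tests therefore demonstrate correctness of the
machinery and the qualitative value of phenotype weighting under the
modularity assumption — not the absolute accuracy to expect on real curated
data.

## Known limitations

* The PRINCE baseline reproduces only the logistic prior + restart walk +
  component score; the original's edge-weight normalization and iterative
  refinement are out of scope, so it is labeled "PRINCE-style".
* Phenotype similarities are consumed as input; computing them from
  phenotype text corpora is out of scope.
* The dense resolvent oracle is guarded at 2 000 nodes; beyond that only the
  sparse iteration is available.
* LCC/COS compare full-length profile vectors; restricting the comparison to
  a candidate subset is not supported.
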