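# diffprio

Disease-gene prioritization on a protein–protein interaction (PPI) network
by **global similarity of diffusion profiles**, with phenotype-similarity
weighting of the disease's start distribution.

## The problem

Linkage and association studies map a disease to a chromosomal interval
containing tens to hundreds of candidate genes.  Because products of genes
causing the same or similar phenotypes tend to interact, the PPI network can
rank those candidates.  Diffusion (random-walk) methods are the strongest
family of network prioritizers; `diffprio` implements a diffusion method
that (i) folds phenotype-similarity information into the walk's restart
vector and (ii) compares *whole* stationary distributions instead of reading
off a single coordinate.

## The method

Let `M` be the column-normalized adjacency matrix of the PPI graph.  A
random walk with restart from start distribution `P0` iterates

```
P_{t+1} = (1 − γ) · M · P_t + γ · P0
```

until `‖P_{t+1} − P_t‖₁ < 10⁻⁶`.  The limit `P∞` is the **diffusion
profile** of the start: for a gene `g`, `P0` is the indicator vector of `g`;
for a disease `d` with causal genes `G(d)`, the start is enriched with the
causal genes of phenotypically similar diseases,

```
D̃0 = D0 + λ · Σᵢ δ(d, dᵢ) · Sim(d, dᵢ) · D0ⁱ ,   δ(d, dᵢ) = 1 iff Sim(d, dᵢ) ≥ 0.3
```

where `D0` (resp. `D0ⁱ`) puts equal mass on each causal gene of `d` (resp.
`dᵢ`) and `Sim` is a MimMiner-style text-mining similarity in [0, 1].
Candidates are ranked by the similarity of their profile to the disease's —
Pearson correlation (**DP_LCC**) or cosine (**DP_COS**).  Two classical
baselines are included: **RWR** (the candidate's component of the unweighted
disease walk) and a **PRINCE-style** scorer (logistic phenotype prior
`L(x) = 1/(1 + e^(−15x + log 9999))`, then component score).  Defaults
`γ = 0.25`, `λ = 0.5`.

The evaluation harness performs leave-one-out cross-validation of each known
association against 99 random or artificial-linkage-interval (genomically
nearest) control genes and reports top-1 precision (PRE), rank-ratio ROC/AUC
on a 0.01 threshold grid, and precision–recall curves.  A synthetic-data
generator produces coherent network/association/similarity/position bundles
with planted, phenotype-clustered disease modules so the whole pipeline is
testable without any external downloads.

## Worked example

```
$ diffprio simulate --outdir demo/bundle --seed 1
wrote bundle to demo/bundle (300 genes, 1210 interactions, 20 diseases)

$ diffprio cv --network demo/bundle/network.tsv \
    --associations demo/bundle/associations.tsv \
    --similarities demo/bundle/similarities.tsv \
    --method dp_lcc --seed 1 --outdir demo/cv
{"auc": 0.9764309764309764, "control": "random", "gamma": 0.25,
 "lambda": 0.5, "method": "dp_lcc", "n_cases": 60, "n_skipped": 0,
 "pre_count": 25, "pre_proportion": 0.4166666666666667, "seed": 1}
```

Of the 60 leave-one-out cases on this bundle, the held-out causal gene
outranks all 99 random controls in 25 (PRE = 0.417), and the rank-ratio ROC
has AUC 0.976 — far above the 0.5 of a chance ranker, because the bundle
plants cohesive disease modules.  Per-case ranks, ROC and PR points are
written under `demo/cv/`.  Genome-wide prediction of new candidates:

```
$ diffprio rank --network demo/bundle/network.tsv \
    --associations demo/bundle/associations.tsv \
    --similarities demo/bundle/similarities.tsv --disease D000 --top-k 5
disease_id  gene_id  score                rank  method
D000        g00001   0.38764329369993605  1     dp_lcc
D000        g00026   0.3533105892786853   2     dp_lcc
...
```

Genes already associated with D000 are excluded; the score is the Pearson
correlation between each candidate's diffusion profile and D000's weighted
disease profile.  `diffprio sweep` evaluates a γ × λ grid for all four
methods.

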