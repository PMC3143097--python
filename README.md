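# netprio

Degree-aware network-based disease gene prioritization.

Given a confidence-weighted protein–protein interaction (PPI) network, a
set of *seed* genes known to be associated with a disease of interest (or
with phenotypically similar diseases), and a *candidate* set — typically a
linkage interval — `netprio` ranks the candidates by how strongly the
network connects them to the seeds, while correcting for the degree bias
that plagues information-flow methods: hub proteins score highly for
almost any seed set, largely because well-studied proteins accumulate
recorded interactions (ascertainment bias), so raw diffusion scores
systematically bury loosely connected true disease genes.

## The model

The network is an undirected graph G(V, E) with edge reliabilities
w(uv) ∈ (0, 1] and weighted degrees W(v) = Σ_{u∈N(v)} w(uv).  Raw
association scores are steady states of

    x_{t+1} = (1 − r) P x_t + r ρ,

where ρ is the restart vector over the seeds (proportional to the
phenotypic-similarity prior σ(v, D)), r is the restart probability
(default 0.3), and P is either the column-stochastic walk matrix
P(u, v) = w(uv)/W(v) (random walk with restarts, α_RW) or the symmetric
propagation operator P(u, v) = w(uv)/√(W(u)W(v)) (network propagation,
α_NP).  Setting r = 0 yields eigenvector centrality c(v), a pure topology
score.

Three reference models convert raw scores into degree-adjusted ones:

* **α_SD** — z-score of α(v) against an empirical null of n re-runs with
  random seed sets matched to the original seed set's weighted-degree
  distribution (one bucket per seed, nearest degree, one uniform draw per
  bucket);
* **α_CD** — z-score of α(v) against the raw scores of the n non-seed
  genes closest to v in weighted degree;
* **α_EC** — the log-likelihood ratio log(α(v)/c(v)) of association
  versus centrality.

Because adjusted rankings favour peripheral genes and raw rankings favour
hubs, three *uniform prioritization* rules merge them: per-gene by the
gene's own degree against a threshold λ (raw if W(v) ≥ λ), optimistically
(best of the two ranks), or globally by the mean seed degree — the
default, motivated by the observation that genes of the same disease tend
to have similar degrees.

A leave-one-out benchmark removes each known disease gene, rebuilds the
prior, forms an artificial linkage interval (the target plus its 99
genomically nearest non-seed neighbours), and records the target's rank
and single-positive ROC area (N − rank)/(N − 1), stratified at the mean
weighted degree m.  A seeded synthetic generator (scale-free network,
planted proximity-based disease modules, similarity matrix, gene
positions, labelled edge features for the logistic reliability model)
makes the whole pipeline runnable without any external data.

## Worked example

Generate a synthetic instance and run the benchmark with the default
combination (centrality adjustment + seed-degree merge):

```sh
$ netprio fixtures --out-dir demo/fix --seed 7 --nodes 500 --diseases 20
wrote 500 genes / 1572 edges, 20 diseases -> demo/fix

$ netprio evaluate --network demo/fix/network.tsv \
    --associations demo/fix/associations.tsv \
    --similarity demo/fix/similarity.tsv \
    --positions demo/fix/positions.bed \
    --adjust centrality --uniform seed --seed 1 --out-dir demo/eval
109 experiments: avg rank 4.99, AUC 0.960 -> demo/eval
```

`demo/eval/summary.json` reports the aggregates — overall average rank
4.99 of 100 and AUROC 0.960, with the low-degree stratum (W ≤ m = 3.58,
75 targets) at average rank 6.05 and the high-degree stratum (34 targets)
at 2.65: loosely connected targets are harder, which is exactly the gap
the adjustments narrow.  Per-experiment ranks are in
`demo/eval/experiments.tsv`.

Ranking all non-seed genes for one disease:

```sh
$ netprio score --network demo/fix/network.tsv \
    --associations demo/fix/associations.tsv \
    --similarity demo/fix/similarity.tsv \
    --disease D00 --adjust centrality --uniform seed --out demo/D00.tsv
wrote ranking of 403 candidates to demo/D00.tsv

$ head -4 demo/D00.tsv
rank  gene   raw_score       adjusted_score  raw_rank  adj_rank  branch_used
1     G106   0.03629292081   2.223793173     1         1         adj
2     G101   0.02419851261   1.780878857     2         2         adj
3     G171   0.009106715031  1.701517541     10        3         adj
```

Each row shows the candidate's raw diffusion score, its centrality
log-ratio, both component ranks, and which branch the merge rule used
(here the seed set is loosely connected, so the adjusted ranking was
chosen for all genes; G171 rises from raw rank 10 to 3 once its score is
normalized by its centrality).

The same pipeline is available as a library — see
`netprio.run_loo_benchmark`, `netprio.propagate`,
`netprio.adjust_seed_degree` and friends.

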