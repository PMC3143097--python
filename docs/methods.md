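# Methods

## Diffusion model

Association scores are fixed points of x = (1 − r)·P·x + r·ρ.  With the
column-stochastic walk operator (`RW`), the fixed point is the stationary
distribution of a random walk that restarts at seed genes with
probability r per step; every iterate, and hence the fixed point, sums
to 1 when ρ does.  With the symmetric operator (`NP`), flow is normalized
by both endpoints' weighted degrees (spectral radius ≤ 1) and the fixed
point is reported without renormalization.  The restart vector is always
normalized to unit mass before iteration so that raw scores are
comparable across diseases.

* **r = 0.3** by default.  Performance of both diffusion variants is flat
  in r except for very small values, where scores collapse onto pure
  centrality; 0.3 is the standard operating point for this family of
  methods.
* **Convergence**: iteration stops when successive iterates differ by
  less than 1e-9 in L1 norm (cap 10,000 iterations; exceeding it raises,
  carrying the last residual).  For networks up to 2,000 nodes
  (configurable) the solver instead factorizes I − (1 − r)P once (sparse
  LU) and solves exactly; the two routes agree within the iteration
  tolerance, and the factorization is reused across the many restart
  vectors of an empirical null.  r = 1 returns ρ; r = 0 is rejected in
  `propagate` and served by `centrality`.
* **Centrality** is computed by power iteration from the uniform vector
  with L1 normalization (tolerance 1e-12).  On a weighted undirected
  graph the stationary law is W(v)/ΣW, which the tests use as an
  independent cross-check.  Bipartite-like structure makes successive
  iterates oscillate with period two; the implementation then averages
  the two alternating iterates (the oscillating mode cancels, leaving an
  error below half the tolerance) and warns only when the oscillation is
  genuinely large.

## Priors and seed sets

σ(v, D) is the maximum phenotypic similarity between D and any disease
v is associated with, passed through the logistic squashing
L(x) = 1/(1 + exp(−15x + log 9999)), the convention of the
network-propagation literature: L(0) = 1e-4, L(1) ≈ 0.997, so direct
associations dominate while weakly similar diseases retain a small
prior.  The parameters, an identity transform, and a hard similarity
cutoff γ are all configurable.

Seed-set *membership* and σ *values* are distinct concerns.  With the
logistic alone, every gene associated with any disease becomes a (very
weak) seed; the per-disease mean seed degree then degenerates to a global
constant and the seed-degree merge rule cannot discriminate.  The
benchmark therefore applies γ = 0.3 by default — only diseases with
similarity above 0.3 contribute seed genes, the empirically informative
range reported for text-mined phenotype similarity — while `build_prior`
keeps γ optional for library use.

## Degree-aware adjustments

All three adjustments rescore a raw vector α:

* **Seed-degree null (α_SD)** — one bucket per seed; every gene joins the
  bucket of the seed nearest in weighted degree (exact ties broken
  randomly; each seed stays in its own bucket).  A null seed set draws
  one gene per bucket uniformly; each sampled gene inherits the σ of the
  bucket's original seed (`sigma_mode="match"`, preserving the restart
  profile; a uniform-mass mode exists).  The adjusted score is
  (α − μ̂)/ŝ over n = 1000 re-propagations by default (the empirical-null
  size used throughout this method family), with the sample standard
  deviation (n − 1 denominator) floored at ε = 1e-12.  Original seeds
  remain eligible in the sampling pool; a flag excludes them.
* **Candidate-degree null (α_CD)** — each gene is z-scored against the
  raw scores of the n genes nearest to it in weighted degree (self
  excluded, boundary ties by identifier, n capped by the pool).  The
  current seed set never serves as peers: seeds are known positives whose
  scores carry restart mass, and on small networks a handful of
  high-score seeds inside a peer window inflates the null standard
  deviation enough to bury exactly the low-degree targets the adjustment
  exists to rescue.  At literature scale (a thousand peers drawn from
  ~9,000 genes with ~10 seeds) this contamination is negligible, which is
  presumably why the question never arose there.
* **Centrality ratio (α_EC)** — log((α + ε)/(c + ε)) with pseudo-count
  ε = 1e-16 guarding exact zeros.

Adjusted scores are compared only by rank, so no multiple-testing
correction is applied.

## Uniform prioritization

Raw and adjusted rankings (descending score, ties to the smaller
identifier) are merged by one of three rules: per-gene degree threshold
(raw branch when W(v) ≥ λ — the inequality is non-strict, a choice this
package fixes explicitly), optimistic minimum, or the global seed-degree
rule (raw for all genes when the mean seed degree reaches λ).  λ defaults
to the mean weighted degree m of all network genes.  Provisional merged
ranks are finalized into a bijection onto 1..|C|: equal provisional ranks
are ordered by each gene's unused ranking, remaining ties
lexicographically.  The default pipeline is centrality adjustment with
the seed-degree merge.

## Reliability model

Edge confidence is a logistic regression on expression correlation (X1),
the hypergeometric mutual clustering coefficient (X2 = −log P[#common
neighbours ≥ observed], computed over a universe of |V| − 2 genes with
the endpoints excluded from each other's neighbourhoods), and a
co-localization indicator (X3).  Fitting uses the unpenalized maximum
likelihood; (quasi-)complete separation is detected through exploding
coefficients and falls back to an L2-regularized fit with a warning.  A
resampled protocol (draw n_pos/n_neg training edges, refit, average
coefficients over repetitions) mirrors how gold-standard positive and
negative catalogs are subsampled in practice; averaging was chosen over
best-of selection since repetition-level likelihoods are not comparable
across resamples.

## Evaluation protocol

Leave-one-out over every (disease, gene) pair for diseases with at least
three network-mapped genes.  The target is removed from **every**
disease's association set — not only the disease under evaluation — so it
cannot receive restart mass through a similar disease.  The candidate set
is the target plus its 99 genomically nearest same-chromosome non-seed
genes (midpoint distance, ties by identifier).  Candidates missing from
the network score 0 and rank after all scored genes, alphabetically among
themselves.  Reported metrics: average target rank, mean single-positive
AUC ((N − rank)/(N − 1), identical to the explicit threshold sweep),
top 1% (rank 1 in a 100-gene interval) and top 5% (rank ≤ 5), overall and
stratified at m.

## Synthetic data

The generator emulates, at desk scale, the corpus this method family is
run on: a Barabási–Albert network (500 genes, attachment 3, edge/node
ratio ≈ 3 versus ≈ 3.7 in curated human PPI snapshots) with edge
reliabilities Beta(2, 1.5) (mean 0.57, so the mean weighted degree lands
near the ≈ 4.2 reported for reliability-weighted human PPI data); 20
diseases (40 in the benchmark runs, giving ≥ 200 leave-one-out
experiments) of 3–9 genes (mean ≈ 6, matching curated disease-gene
counts); a single synthetic chromosome with shuffled, non-overlapping
gene intervals; and a labelled edge-feature table.

Disease modules are planted as *proximity regions*: a start node is drawn
near a per-disease weighted-degree percentile (percentile centers
Beta(1.5, 3) — low-degree-biased overall, with spread, so diseases are
internally degree-homogeneous, the regularity the seed-degree merge rule
exploits), and module genes are sampled from its 2-hop neighbourhood
ball; intra-module edges are added with probability 0.3.  Members are
therefore pairwise within 4 hops but mostly not adjacent.  This mirrors
curated interaction data, where genes of one disease tend to be close in
the network while direct interactions between them are largely
unrecorded; it is also what creates the regime the adjustments address —
with fully interconnected planted cliques, raw diffusion ranks nearly
every held-out target first and degree bias never manifests.  Phenotypic
similarity is overlap-based (0.9 · |S_i ∩ S_j| / min(|S_i|, |S_j|));
generation is byte-deterministic per seed.

What the generator does **not** emulate: identifier noise and mapping
loss, multiple chromosomes and gene-density variation, disease modules
larger than 9 genes, correlated measurement error between edge
reliability and degree, and the literature's full network scale.  Tests
passing on these fixtures show the algorithms behave as specified and
reproduce the qualitative degree-bias phenomenology; they are not
evidence about absolute performance on real corpora.

## Numerical and degenerate-input choices

Duplicate/reciprocal edge records keep the maximum weight (duplicates
arise from merged source databases; reliability semantics favour the best
evidence).  Self-loops are dropped; nodes without edges are absent by
construction; node order is lexicographic everywhere.  Zero-variance
empirical nulls hit the ε floor and yield finite (near-zero) z-scores.
`assign_buckets` breaks exact degree ties by per-(node, seed) uniform
draws — deterministic for a fixed generator.  Benchmark problem sizes
(500 nodes, n = 100 nulls, 200+ experiments) were chosen so a full
method comparison runs in about a minute on one CPU.

## Known limitations

* The bucket sampler's total-degree matching is exact only when buckets
  are symmetric around their seeds.  On heavy-tailed networks the
  highest-degree seed's bucket absorbs the entire upper degree tail, and
  the expected sampled total exceeds the true seed total by 10–25% for
  typical small seed sets (computed in closed form from bucket means).
  The matching property should be relied on only for concentrated degree
  distributions or seed sets anchored across the degree range.
* z-score adjustments amplify noise where the null standard deviation is
  poorly resolved (genes far from all seeds); small empirical nulls
  (n ≪ 1000) make adjusted rankings of such genes a lottery among
  near-zero scores.
* The seed-degree merge is global per disease; it inherits the
  within-disease degree-homogeneity assumption and can pick the wrong
  branch for diseases whose genes straddle the threshold.
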