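"""Degree-aware statistical adjustment of raw diffusion scores.

Raw diffusion scores confound disease association with network centrality:
hub genes score high for almost any seed set, a consequence of
ascertainment bias in interaction data.  Three reference models convert a
raw score alpha(v) into a degree-adjusted score:

* **seed-degree model** (``adjusted_sd``): the empirical null is alpha(v)
  recomputed under n random seed sets matched to the original seed set's
  weighted-degree distribution (one bucket per seed, nearest weighted
  degree, one uniform draw per bucket); the adjusted score is the z-score
  (alpha - mean) / sd over the replicates.
* **candidate-degree model** (``adjusted_cd``): the null for gene v is the
  set of raw scores of the n genes whose weighted degree is closest to
  W(v), under the *original* seed set; again a z-score.
* **centrality likelihood ratio** (``adjusted_ec``): the log-ratio
  log((alpha(v) + eps) / (c(v) + eps)) of the association score to the
  eigenvector centrality — the walk's score with an empty seed set.

Scores are only compared by rank afterwards, so no multiple-testing
correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .diffusion import DiffusionConfig, Propagator, ScoreVector
from .network import TransitionMatrix, WeightedNetwork
from .priors import DiseasePrior, build_restart_vector

logger = logging.getLogger(__name__)

__all__ = [
    "BucketAssignment",
    "adjust_candidate_degree",
    "adjust_centrality",
    "adjust_seed_degree",
    "assign_buckets",
    "candidate_degree_peers",
    "sample_degree_matched_seeds",
]

SD_FLOOR = 1e-12  # floor on the null standard deviation
EC_EPS = 1e-16  # pseudo-count in the centrality log-ratio


@dataclass
class BucketAssignment:
    """Partition of the node set into one bucket per seed gene.

    Every node belongs to the bucket of the seed with nearest weighted
    degree (exact ties broken randomly); each seed sits in its own bucket.
    """

    buckets: dict[str, list[str]]  # seed -> sorted member nodes

    @property
    def seeds(self) -> list[str]:
        return sorted(self.buckets)

    def __len__(self) -> int:
        return len(self.buckets)


def assign_buckets(
    net: WeightedNetwork,
    seeds: Iterable[str],
    rng: np.random.Generator | None = None,
) -> BucketAssignment:
    """Assign every node to the seed with nearest weighted degree.

    A node exactly equidistant (in |W(seed) - W(node)|) from several seeds
    is assigned to one of them at random; the assignment is deterministic
    for a fixed generator.  Each seed is always a member of its own bucket.
    """
    rng = np.random.default_rng() if rng is None else rng
    seeds = sorted(set(seeds))
    if not seeds:
        raise ValueError("seed set is empty")
    for s in seeds:
        if s not in net:
            raise KeyError(s)
    wdeg = net.weighted_degrees()
    idx = net.node_index
    w_seeds = np.array([wdeg[idx[s]] for s in seeds])
    dist = np.abs(wdeg[:, np.newaxis] - w_seeds[np.newaxis, :])  # nodes x seeds
    dmin = dist.min(axis=1)
    tie_mask = dist == dmin[:, np.newaxis]
    # random tie-break: highest random draw among the tied seeds wins
    draws = rng.random(dist.shape)
    choice = np.where(tie_mask, draws, -1.0).argmax(axis=1)
    buckets: dict[str, list[str]] = {s: [] for s in seeds}
    seed_pos = {s: j for j, s in enumerate(seeds)}
    for i, g in enumerate(net.nodes):
        if g in seed_pos:
            continue  # seeds pinned to their own buckets below
        buckets[seeds[choice[i]]].append(g)
    for s in seeds:
        buckets[s].append(s)
        buckets[s].sort()
    return BucketAssignment(buckets=buckets)


def sample_degree_matched_seeds(
    buckets: BucketAssignment,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Draw one node uniformly from each bucket.

    Returns a mapping original seed -> sampled node.  The sampled set has
    exactly one representative per seed, so its total weighted degree is
    close to the original seed set's in expectation.
    """
    rng = np.random.default_rng() if rng is None else rng
    return {
        seed: members[rng.integers(len(members))]
        for seed, members in sorted(buckets.buckets.items())
    }


def adjust_seed_degree(
    net: WeightedNetwork,
    prior: DiseasePrior,
    P: TransitionMatrix,
    config: DiffusionConfig | None = None,
    n: int = 1000,
    rng: np.random.Generator | None = None,
    sigma_mode: str = "match",
    exclude_original_seeds: bool = False,
    sd_floor: float = SD_FLOOR,
    return_replicates: bool = False,
):
    """z-score raw scores against degree-matched random seed sets (alpha_SD).

    For each of ``n`` replicates a random seed set is drawn (one node per
    degree bucket) and the diffusion is re-run with that set's restart
    vector; the adjusted score of every gene is
    (alpha - mean) / sd over the replicates, with the standard deviation
    (n-1 denominator) floored at ``sd_floor``.

    ``sigma_mode="match"`` gives each sampled node the sigma of the
    original seed whose bucket it came from, preserving the restart mass
    profile; ``"uniform"`` gives all sampled nodes equal mass.
    ``exclude_original_seeds=True`` removes original seeds from the
    sampling pool of other buckets (each seed always remains available in
    its own bucket if it would otherwise be empty).

    Returns the adjusted :class:`ScoreVector`, or
    ``(scores, replicates)`` with the (n, n_nodes) replicate matrix when
    ``return_replicates`` is set.
    """
    if n < 2:
        raise ValueError("need n >= 2 null replicates")
    if sigma_mode not in ("match", "uniform"):
        raise ValueError(f"unknown sigma_mode: {sigma_mode!r}")
    rng = np.random.default_rng() if rng is None else rng
    config = config or DiffusionConfig()
    prop = Propagator(P, config)

    rho = build_restart_vector(prior, P.nodes)
    alpha = prop.solve(rho)

    buckets = assign_buckets(net, prior.seeds, rng)
    if exclude_original_seeds:
        originals = prior.seeds
        pruned = {}
        for seed, members in buckets.buckets.items():
            kept = [m for m in members if m not in originals]
            pruned[seed] = kept if kept else [seed]
        buckets = BucketAssignment(buckets=pruned)

    index = net.node_index
    replicates = np.empty((n, P.n))
    for i in range(n):
        sampled = sample_degree_matched_seeds(buckets, rng)
        rho_i = np.zeros(P.n)
        for orig_seed, node in sampled.items():
            mass = prior.sigma[orig_seed] if sigma_mode == "match" else 1.0
            rho_i[index[node]] += mass
        rho_i /= rho_i.sum()
        replicates[i] = prop.solve(rho_i)

    mu = replicates.mean(axis=0)
    sd = replicates.std(axis=0, ddof=1)
    z = (alpha - mu) / np.maximum(sd, sd_floor)
    scores = ScoreVector(nodes=P.nodes, values=z, meaning="adjusted_sd")
    if return_replicates:
        return scores, replicates
    return scores


def candidate_degree_peers(
    net: WeightedNetwork,
    n: int = 1000,
    candidates: Sequence[str] | None = None,
    exclude: Iterable[str] = (),
) -> dict[str, np.ndarray]:
    """Index arrays of each candidate's n nearest weighted-degree peers.

    Peers exclude the candidate itself and any gene in ``exclude``
    (typically the current seed set, whose scores carry restart mass and
    would contaminate the empirical null); boundary ties in |W(v) - W(u)|
    are broken by gene identifier.  n is capped by the available pool.
    """
    wdeg = net.weighted_degrees()
    nodes = net.nodes
    idx = net.node_index
    excluded = np.zeros(len(nodes), dtype=bool)
    for g in exclude:
        if g in idx:
            excluded[idx[g]] = True
    pool = len(nodes) - int(excluded.sum())
    n = min(n, pool - 1)
    if n < 2:
        raise ValueError("fewer than 2 eligible degree peers after exclusions")
    if candidates is None:
        candidates = nodes
    name_rank = np.arange(len(nodes))  # nodes already sorted lexicographically
    peers: dict[str, np.ndarray] = {}
    for g in candidates:
        if g not in idx:
            continue
        i = idx[g]
        dist = np.abs(wdeg - wdeg[i])
        dist[i] = np.inf  # exclude self
        dist[excluded] = np.inf
        order = np.lexsort((name_rank, dist))
        peers[g] = order[:n]
    return peers


def adjust_candidate_degree(
    net: WeightedNetwork,
    alpha: ScoreVector,
    n: int = 1000,
    candidates: Sequence[str] | None = None,
    sd_floor: float = SD_FLOOR,
    peers: Mapping[str, np.ndarray] | None = None,
    exclude: Iterable[str] = (),
) -> ScoreVector:
    """z-score each gene against its weighted-degree peers (alpha_CD).

    The null for gene v is the raw-score sample of the n genes nearest to
    v in weighted degree (under the same, original seed set); the adjusted
    score is (alpha(v) - mean) / sd with the n-1 denominator and the
    ``sd_floor`` guard.  Genes outside ``candidates`` get NaN.  Genes in
    ``exclude`` (the seed set) never serve as peers.

    A precomputed ``peers`` mapping (from :func:`candidate_degree_peers`)
    can be supplied when the same network is adjusted repeatedly.
    """
    if n < 2:
        raise ValueError("need n >= 2 degree peers")
    if tuple(alpha.nodes) != net.nodes:
        raise ValueError("score vector is not aligned with the network")
    if peers is None:
        peers = candidate_degree_peers(net, n, candidates, exclude=exclude)
    values = np.full(net.n_nodes, np.nan)
    idx = net.node_index
    for g, peer_idx in peers.items():
        sample = alpha.values[peer_idx]
        mu = sample.mean()
        sd = sample.std(ddof=1)
        values[idx[g]] = (alpha.values[idx[g]] - mu) / max(sd, sd_floor)
    return ScoreVector(nodes=net.nodes, values=values, meaning="adjusted_cd")


def adjust_centrality(
    alpha: ScoreVector,
    cent: ScoreVector,
    eps: float = EC_EPS,
) -> ScoreVector:
    """Centrality log-likelihood ratio: log((alpha + eps) / (c + eps)).

    ``alpha`` is the association score with restarts (r > 0); ``cent`` the
    eigenvector centrality (r = 0), i.e. the likelihood of association
    with an arbitrary gene.  Both must be non-negative and share the node
    order.
    """
    if tuple(alpha.nodes) != tuple(cent.nodes):
        raise ValueError("score vectors are not over the same node order")
    if (alpha.values < 0).any() or (cent.values < 0).any():
        raise ValueError("centrality log-ratio requires non-negative inputs")
    values = np.log((alpha.values + eps) / (cent.values + eps))
    return ScoreVector(nodes=alpha.nodes, values=values, meaning="adjusted_ec")
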