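"""Rankings and uniform prioritization (rank merging).

Candidate genes are sorted by descending score to obtain a 1-based
ranking (rank 1 = strongest candidate).  Raw and degree-adjusted rankings
disagree systematically — the raw ranking favours hubs, the adjusted
ranking favours peripheral genes — so three merging strategies produce a
single uniform ranking R_UNI:

* ``candidate_degree`` — per gene: use the raw rank if the gene's own
  weighted degree is at least the threshold lambda, else the adjusted
  rank ("rank a hub by its raw score, a peripheral gene by its
  significance");
* ``optimistic`` — per gene: the better (minimum) of the two ranks;
* ``seed_degree`` — globally: the raw ranking for every gene if the mean
  weighted degree of the seed set reaches lambda, else the adjusted
  ranking (known genes of a disease tend to have degrees similar to the
  unknown one).

Provisional merged ranks may collide; they are finalized into a bijection
onto 1..|C| ordering equal provisional ranks by each gene's unused
ranking, remaining ties lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .diffusion import ScoreVector

__all__ = [
    "MergePolicy",
    "Ranking",
    "merge_rankings",
    "rank_candidates",
    "rank_descending",
]

STRATEGIES = ("candidate_degree", "optimistic", "seed_degree")


@dataclass
class Ranking:
    """1-based ranking of a candidate set; rank 1 is the best candidate."""

    ranks: dict[str, int]
    source: str = "RAW"
    branch: dict[str, str] = field(default_factory=dict)  # gene -> raw|adj

    @property
    def candidates(self) -> set[str]:
        return set(self.ranks)

    def __getitem__(self, gene: str) -> int:
        return self.ranks[gene]

    def __len__(self) -> int:
        return len(self.ranks)

    def ordered(self) -> list[str]:
        return sorted(self.ranks, key=self.ranks.get)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"rank": r, "gene": g, "branch_used": self.branch.get(g, "")}
            for g, r in sorted(self.ranks.items(), key=lambda kv: kv[1])
        ]
        return pd.DataFrame(rows)


@dataclass
class MergePolicy:
    """How to merge a raw and an adjusted ranking.

    ``lam`` is the degree threshold (default: callers pass the network's
    mean weighted degree); ``weighted_degrees`` maps gene -> W(v) (genes
    missing from it count as degree 0); ``seeds`` is required by the
    seed_degree strategy.
    """

    strategy: str
    lam: float
    weighted_degrees: Mapping[str, float] | None = None
    seeds: Iterable[str] | None = None

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}"
            )
        if self.lam < 0:
            raise ValueError("degree threshold lambda must be >= 0")


def rank_descending(
    scores: ScoreVector | Mapping[str, float],
    candidates: Sequence[str],
    source: str = "RAW",
) -> Ranking:
    """Rank candidates by descending score; exact ties go to the
    lexicographically smaller identifier."""
    get = scores.get if hasattr(scores, "get") else scores.__getitem__
    pairs = []
    for g in candidates:
        s = get(g)
        if s is None:
            raise KeyError(f"no score for candidate {g}")
        pairs.append((g, float(s)))
    pairs.sort(key=lambda gs: (-gs[1], gs[0]))
    return Ranking(
        ranks={g: i + 1 for i, (g, _) in enumerate(pairs)}, source=source
    )


def rank_candidates(
    scores: ScoreVector,
    candidates: Sequence[str],
    source: str = "RAW",
) -> Ranking:
    """Rank a candidate set that may contain genes without a score.

    Unscored candidates (absent from the network) are placed after every
    scored gene, alphabetically among themselves.
    """
    scored = [g for g in candidates if scores.get(g) is not None]
    unscored = sorted(g for g in candidates if scores.get(g) is None)
    ranking = rank_descending(scores, scored, source=source)
    base = len(scored)
    for j, g in enumerate(unscored):
        ranking.ranks[g] = base + j + 1
    return ranking


def merge_rankings(
    r_raw: Ranking, r_adj: Ranking, policy: MergePolicy
) -> Ranking:
    """Merge raw and adjusted rankings into a uniform ranking R_UNI.

    Per-gene provisional ranks follow the policy's strategy (degree
    comparisons are non-strict: W >= lambda selects the raw branch); ties
    among equal provisional ranks are broken by the unused ranking, then
    lexicographically, yielding a bijection onto 1..|C|.
    """
    if r_raw.candidates != r_adj.candidates:
        raise ValueError("rankings cover different candidate sets")
    wdeg = policy.weighted_degrees or {}

    if policy.strategy == "seed_degree":
        if policy.seeds is None:
            raise ValueError("seed_degree strategy needs the seed set")
        seeds = list(policy.seeds)
        if not seeds:
            raise ValueError("seed_degree strategy needs a non-empty seed set")
        mean_w = sum(wdeg.get(s, 0.0) for s in seeds) / len(seeds)
        global_branch = "raw" if mean_w >= policy.lam else "adj"

    provisional: list[tuple[int, int, str, str]] = []  # (prov, unused, gene, branch)
    for g in r_raw.candidates:
        rr, ra = r_raw[g], r_adj[g]
        if policy.strategy == "candidate_degree":
            branch = "raw" if wdeg.get(g, 0.0) >= policy.lam else "adj"
        elif policy.strategy == "optimistic":
            branch = "raw" if rr <= ra else "adj"
        else:
            branch = global_branch
        if policy.strategy == "optimistic":
            prov, unused = min(rr, ra), max(rr, ra)
        else:
            prov = rr if branch == "raw" else ra
            unused = ra if branch == "raw" else rr
        provisional.append((prov, unused, g, branch))

    provisional.sort()
    ranks = {g: i + 1 for i, (_, _, g, _) in enumerate(provisional)}
    branch_used = {g: b for (_, _, g, b) in provisional}
    return Ranking(
        ranks=ranks, source=f"UNI_{policy.strategy}", branch=branch_used
    )


def ranking_table(
    r_uni: Ranking,
    r_raw: Ranking,
    r_adj: Ranking,
    raw_scores: ScoreVector | None = None,
    adj_scores: ScoreVector | None = None,
) -> pd.DataFrame:
    """Export table: rank, gene, raw/adjusted scores and ranks, branch."""
    rows = []
    for g in r_uni.ordered():
        rows.append(
            {
                "rank": r_uni[g],
                "gene": g,
                "raw_score": raw_scores.get(g) if raw_scores else None,
                "adjusted_score": adj_scores.get(g) if adj_scores else None,
                "raw_rank": r_raw[g],
                "adj_rank": r_adj[g],
                "branch_used": r_uni.branch.get(g, ""),
            }
        )
    return pd.DataFrame(rows)
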