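"""Disease-specific priors and restart vectors.

The prior association sigma(v, D) of gene v with the disease of interest D
is the maximum phenotypic similarity between D and any disease v is known
to be associated with, passed through a logistic squashing function.  A
gene directly associated with D has raw similarity 1 (phi(D, D) = 1).  The
restart vector rho distributes unit mass over the seed set proportionally
to sigma.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DiseasePrior",
    "DiseaseSimilarity",
    "LogisticTransform",
    "build_prior",
    "build_restart_vector",
    "read_associations",
]


@dataclass(frozen=True)
class LogisticTransform:
    """L(x) = 1 / (1 + exp(slope * x + offset)).

    Defaults slope = -15, offset = log(9999) follow the convention of the
    network-propagation literature: L(0) = 1e-4, L(1) ~ 0.997, so direct
    associations dominate while weakly similar diseases retain a small
    prior.  L is increasing in x for negative slope.
    """

    slope: float = -15.0
    offset: float = math.log(9999.0)

    def __call__(self, x: float) -> float:
        return 1.0 / (1.0 + math.exp(self.slope * x + self.offset))


def identity_transform(x: float) -> float:
    """Pass-through transform, mainly for testing."""
    return x


class DiseaseSimilarity:
    """Symmetric phenotypic similarity phi(d_i, d_j) in [0, 1].

    Stored sparsely; missing pairs have similarity 0 and phi(d, d) = 1
    always.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None,
                 diseases: Iterable[str] = ()):
        self._sim: dict[tuple[str, str], float] = {}
        self._diseases: set[str] = set(diseases)
        if pairs:
            for (a, b), s in pairs.items():
                self.set(a, b, s)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, s: float) -> None:
        s = float(s)
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"similarity out of [0, 1]: phi({a}, {b}) = {s}")
        self._diseases.update((a, b))
        if a == b:
            if s != 1.0:
                raise ValueError(f"phi({a}, {a}) must be 1, got {s}")
            return
        if s > 0.0:
            self._sim[self._key(a, b)] = s

    def phi(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._sim.get(self._key(a, b), 0.0)

    @property
    def diseases(self) -> set[str]:
        return set(self._diseases)

    def __contains__(self, d: str) -> bool:
        return d in self._diseases

    def pairs(self) -> Iterable[tuple[str, str, float]]:
        for (a, b), s in sorted(self._sim.items()):
            yield a, b, s

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DiseaseSimilarity":
        """TSV: disease_a, disease_b, similarity. Missing pairs are 0."""
        out = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                a, b, s = line.split("\t")
                out.set(a, b, float(s))
        return out

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for a, b, s in self.pairs():
                fh.write(f"{a}\t{b}\t{s:.10g}\n")


@dataclass
class DiseasePrior:
    """Seed genes and their prior association with a disease of interest."""

    disease: str
    sigma: dict[str, float] = field(default_factory=dict)  # seed -> sigma in [0,1]

    @property
    def seeds(self) -> set[str]:
        return set(self.sigma)


def read_associations(path: str | Path) -> dict[str, set[str]]:
    """TSV disease_id, gene_id -> mapping disease -> gene set."""
    assocs: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            d, g = line.split("\t")
            assocs.setdefault(d, set()).add(g)
    return assocs


def build_prior(
    assocs: Mapping[str, Iterable[str]],
    sim: DiseaseSimilarity,
    disease: str,
    transform: Callable[[float], float] | None = None,
    network=None,
    gamma: float | None = None,
) -> DiseasePrior:
    """Compute sigma(v, D) for every associated gene.

    For each gene v appearing in any association set, the raw similarity is
    the maximum of phi(D, d) over the diseases d that v is associated with
    (phi(D, D) = 1 for direct associations).  An optional hard cutoff
    ``gamma`` discards similarities <= gamma before the maximum (direct
    associations survive it).  ``transform`` (default
    :class:`LogisticTransform`) maps the raw similarity to sigma; genes
    with sigma > 0 form the seed set.

    If ``network`` is given, genes absent from it are dropped with a
    warning.  Raises ``ValueError("no usable seeds")`` if the seed set
    comes out empty.
    """
    if transform is None:
        transform = LogisticTransform()
    if disease not in sim and disease not in assocs:
        raise KeyError(f"unknown disease: {disease}")
    raw: dict[str, float] = {}
    for d, genes in assocs.items():
        s = sim.phi(disease, d)
        if gamma is not None and d != disease and s <= gamma:
            continue
        for g in genes:
            if s > raw.get(g, -1.0):
                raw[g] = s
    n_dropped = 0
    sigma: dict[str, float] = {}
    for g, x in raw.items():
        if network is not None and g not in network:
            n_dropped += 1
            continue
        val = float(transform(x))
        if val > 0.0:
            sigma[g] = val
    if n_dropped:
        logger.warning(
            "dropped %d associated gene(s) absent from the network", n_dropped
        )
    if not sigma:
        raise ValueError("no usable seeds")
    return DiseasePrior(disease=disease, sigma=sigma)


def build_restart_vector(
    prior: DiseasePrior, node_order: tuple[str, ...] | list[str]
) -> np.ndarray:
    """rho(v) = sigma(v, D) / sum over seeds of sigma, aligned to node_order.

    Seeds absent from ``node_order`` contribute no mass.  Raises if the
    total sigma over the ordered nodes is zero.
    """
    index = {g: i for i, g in enumerate(node_order)}
    rho = np.zeros(len(node_order))
    for g, s in prior.sigma.items():
        i = index.get(g)
        if i is not None:
            rho[i] = s
    total = rho.sum()
    if total <= 0.0:
        raise ValueError("restart vector has zero total seed mass")
    return rho / total
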