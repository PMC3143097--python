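"""Steady-state diffusion scores: random walk with restarts and network
propagation.

Both methods iterate

    x_{t+1} = (1 - r) P x_t + r rho,        x_0 = rho,

where P is one of the two normalized operators of
:mod:`netprio.network`, rho is the restart vector over the seed genes, and
r in (0, 1] is the restart probability balancing prior knowledge (the
seeds) against network topology.  The limit x_inf is the unique solution
of the linear system (I - (1 - r) P) x = r rho, and each gene's entry is
its association score with the disease.

Eigenvector centrality is the r -> 0 limit: the stationary vector of the
column-stochastic walk matrix, a pure topology measure used as the null in
the likelihood-ratio adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import TransitionMatrix, WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ConvergenceError",
    "DiffusionConfig",
    "Propagator",
    "ScoreVector",
    "centrality",
    "propagate",
]


class ConvergenceError(RuntimeError):
    """Iteration failed to converge; carries the last L1 residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class ScoreVector:
    """Per-gene scores aligned to a fixed node ordering.

    ``meaning`` records what the values are: one of ``raw_rw``, ``raw_np``,
    ``centrality``, ``adjusted_sd``, ``adjusted_cd``, ``adjusted_ec``.
    Raw and centrality vectors are non-negative; adjusted vectors are
    real-valued z-scores or log-ratios and may be negative.
    """

    nodes: tuple[str, ...]
    values: np.ndarray
    meaning: str = "raw_rw"
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.nodes),):
            raise ValueError("values must align with nodes")
        if self._index is None:
            self._index = {g: i for i, g in enumerate(self.nodes)}

    def __getitem__(self, gene: str) -> float:
        return float(self.values[self._index[gene]])

    def get(self, gene: str, default=None):
        i = self._index.get(gene)
        return default if i is None else float(self.values[i])

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def to_dict(self) -> dict[str, float]:
        return {g: float(x) for g, x in zip(self.nodes, self.values)}

    def write_tsv(self, path) -> None:
        """Write (gene, score) sorted by descending score."""
        order = np.lexsort((np.array(self.nodes), -self.values))
        with open(path, "w", encoding="utf-8") as fh:
            for i in order:
                fh.write(f"{self.nodes[i]}\t{self.values[i]:.10g}\n")


@dataclass
class DiffusionConfig:
    """Diffusion parameters.

    r=0.3 is the default restart probability (performance is flat in r
    except for very small values); tolerance is the L1 distance between
    successive iterates at which iteration stops.  ``method`` selects the
    solver: ``"auto"`` uses a direct sparse factorization below
    ``direct_threshold`` nodes (identical to the iterative fixed point
    within tolerance), ``"iterative"`` forces power iteration.
    """

    r: float = 0.3
    tol: float = 1e-9
    max_iter: int = 10_000
    method: str = "auto"  # auto | iterative | direct
    direct_threshold: int = 2000

    def __post_init__(self):
        if not (0.0 <= self.r <= 1.0):
            raise ValueError("restart probability r must be in [0, 1]")
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def _check_rho(rho: np.ndarray, n: int) -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    if rho.shape != (n,):
        raise ValueError(f"restart vector has shape {rho.shape}, expected ({n},)")
    if (rho < 0).any():
        raise ValueError("restart vector must be non-negative")
    s = rho.sum()
    if not np.isclose(s, 1.0, atol=1e-6):
        raise ValueError(f"restart vector must sum to 1 (got {s})")
    return rho


class Propagator:
    """Reusable solver for (I - (1-r) P) x = r rho at fixed P and r.

    Factorizes the system matrix once (sparse LU) so that many restart
    vectors — e.g. the replicates of an empirical null — are each a single
    triangular solve.  Falls back to iteration above the size threshold or
    when ``method="iterative"``.
    """

    def __init__(self, P: TransitionMatrix, config: DiffusionConfig | None = None):
        self.P = P
        self.config = config or DiffusionConfig()
        if self.config.r == 0:
            raise ValueError("r = 0 has no restart fixed point; use centrality()")
        use_direct = self.config.method == "direct" or (
            self.config.method == "auto" and P.n <= self.config.direct_threshold
        )
        self._lu = None
        if use_direct and self.config.r < 1.0:
            system = sp.identity(P.n, format="csc") - (1.0 - self.config.r) * P.matrix
            self._lu = spla.splu(system.tocsc())

    def solve(self, rho: np.ndarray) -> np.ndarray:
        rho = _check_rho(rho, self.P.n)
        r = self.config.r
        if r == 1.0:
            return rho.copy()
        if self._lu is not None:
            return self._lu.solve(r * rho)
        return self._iterate(rho)

    def _iterate(self, rho: np.ndarray) -> np.ndarray:
        r = self.config.r
        mat = self.P.matrix
        x = rho.copy()
        residual = np.inf
        for it in range(self.config.max_iter):
            x_next = (1.0 - r) * (mat @ x) + r * rho
            residual = float(np.abs(x_next - x).sum())
            x = x_next
            if residual < self.config.tol:
                logger.debug("diffusion converged in %d iterations", it + 1)
                return x
        raise ConvergenceError(
            f"no convergence in {self.config.max_iter} iterations "
            f"(last L1 residual {residual:.3e})",
            residual,
        )


def propagate(
    P: TransitionMatrix,
    rho: np.ndarray,
    config: DiffusionConfig | None = None,
) -> ScoreVector:
    """Fixed point of x <- (1-r) P x + r rho.

    ``rho`` must be non-negative, sum to 1, and be indexed by ``P.nodes``.
    With the RW operator the result is a probability vector (sums to 1);
    with the NP operator it is the un-renormalized propagation fixed point.
    r = 1 returns rho exactly; r = 0 is rejected (use :func:`centrality`).
    """
    config = config or DiffusionConfig()
    values = Propagator(P, config).solve(rho)
    meaning = "raw_rw" if P.kind == "RW" else "raw_np"
    return ScoreVector(nodes=P.nodes, values=values, meaning=meaning)


def centrality(
    net: WeightedNetwork,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> ScoreVector:
    """Eigenvector centrality: stationary vector of the RW walk matrix.

    Power iteration from the uniform vector with L1 normalization each
    step.  On bipartite (periodic) structure the iterates oscillate with
    period two; the two alternating iterates are then averaged with a
    warning.  Entries are positive on a connected network and sum to 1.
    """
    P = net.transition_matrix("RW")
    mat = P.matrix
    n = P.n
    x = np.full(n, 1.0 / n)
    x_prev = x
    for it in range(max_iter):
        x_next = mat @ x
        x_next /= x_next.sum()
        diff1 = np.abs(x_next - x).sum()
        if diff1 < tol:
            return ScoreVector(nodes=P.nodes, values=x_next, meaning="centrality")
        # period-2 behavior: every other iterate has converged while
        # successive iterates still alternate.  Averaging the alternating
        # pair cancels the oscillating mode (error below tol/2); warn only
        # on genuine oscillation (bipartite structure), not on the slow
        # alternating decay of a negative subdominant eigenvalue.
        if it > 0 and np.abs(x_next - x_prev).sum() < tol:
            if diff1 >= 100 * tol:
                warnings.warn(
                    "periodic (bipartite-like) structure detected in power "
                    "iteration; averaging the two alternating iterates",
                    RuntimeWarning,
                    stacklevel=2,
                )
            avg = 0.5 * (x_next + x)
            avg /= avg.sum()
            return ScoreVector(nodes=P.nodes, values=avg, meaning="centrality")
        x_prev = x
        x = x_next
    raise ConvergenceError(
        f"centrality power iteration did not converge in {max_iter} steps",
        float(np.abs(x - x_prev).sum()),
    )
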