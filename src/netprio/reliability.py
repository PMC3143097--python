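"""Logistic-regression reliability scoring of interactions.

The confidence weight of an interaction u-v is the estimated probability
of a true interaction given three edge features:

* X1 — Pearson correlation of the coding genes' expression profiles,
* X2 — the endpoints' "small-world" mutual clustering coefficient (here
  the hypergeometric neighborhood-overlap statistic
  -log P[#common neighbors >= observed]),
* X3 — subcellular co-localization (1 if the pair shares an annotated
  compartment).

Coefficients beta0..beta3 are fit by maximum likelihood on labelled
positive/negative edges; the reliability of an edge is
w = 1 / (1 + exp(-(beta0 + beta1 X1 + beta2 X2 + beta3 X3))), always in
(0, 1), so scored edge lists plug directly into the network loader.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.linear_model import LogisticRegression

from .network import WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ReliabilityModel",
    "fit_reliability_model",
    "fit_reliability_model_resampled",
    "mutual_clustering_feature",
    "read_feature_table",
    "score_edge_reliability",
    "score_edge_table",
]

FEATURES = ("x1", "x2", "x3")
_SEPARATION_COEF = 30.0  # |beta| beyond this flags quasi-complete separation


@dataclass(frozen=True)
class ReliabilityModel:
    beta0: float
    beta1: float
    beta2: float
    beta3: float

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3])


def mutual_clustering_feature(net: WeightedNetwork, u: str, v: str) -> float:
    """Hypergeometric mutual clustering coefficient of a node pair.

    With k observed common neighbors, n_u = |N(u) \\ {v}|,
    n_v = |N(v) \\ {u}| and a universe of |V| - 2 other nodes, the feature
    is -log P[X >= k] for X hypergeometric — large when the neighborhoods
    overlap more than chance, exactly 0 when they share no neighbor.
    Symmetric in u, v.
    """
    if u == v:
        raise ValueError("mutual clustering feature is undefined for u == v")
    nu = net.neighbors(u) - {v}
    nv = net.neighbors(v) - {u}
    k = len(nu & nv)
    universe = net.n_nodes - 2
    if universe <= 0:
        return 0.0
    p_tail = float(hypergeom.sf(k - 1, universe, len(nu), len(nv)))
    return -np.log(max(p_tail, np.finfo(float).tiny))


def _design(features: pd.DataFrame) -> np.ndarray:
    return features.loc[:, list(FEATURES)].to_numpy(dtype=float)


def fit_reliability_model(features: pd.DataFrame) -> ReliabilityModel:
    """Maximum-likelihood logistic fit on a labelled feature table.

    ``features`` needs columns x1, x2, x3 and a 0/1 ``label`` column with
    both classes present.  On (quasi-)complete separation the unpenalized
    MLE diverges; this is detected via exploding coefficients and the fit
    falls back to an L2-regularized solution with a warning.
    """
    if "label" not in features.columns:
        raise ValueError("feature table has no 'label' column")
    y = features["label"].to_numpy(dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("training data must contain both labels 0 and 1")
    X = _design(features)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=5000, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lbfgs line-search chatter on separation
        clf.fit(X, y)
    coefs = np.concatenate(([clf.intercept_[0]], clf.coef_[0]))
    if np.abs(coefs).max() > _SEPARATION_COEF:
        warnings.warn(
            "complete or quasi-complete separation detected; falling back "
            "to an L2-regularized fit",
            RuntimeWarning,
            stacklevel=2,
        )
        clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=5000)
        clf.fit(X, y)
        coefs = np.concatenate(([clf.intercept_[0]], clf.coef_[0]))
    return ReliabilityModel(*map(float, coefs))


def fit_reliability_model_resampled(
    features: pd.DataFrame,
    n_pos: int = 1000,
    n_neg: int = 1000,
    reps: int = 1000,
    rng: np.random.Generator | None = None,
) -> ReliabilityModel:
    """Average coefficients over repeated fits on resampled training sets.

    Each repetition draws ``n_pos`` positive and ``n_neg`` negative edges
    (with replacement if a class is smaller than requested) and refits;
    the final model averages the coefficient vectors, stabilizing the fit
    when gold-standard positives and negatives are sampled from larger
    catalogs.
    """
    rng = np.random.default_rng() if rng is None else rng
    pos = features[features["label"] == 1]
    neg = features[features["label"] == 0]
    if pos.empty or neg.empty:
        raise ValueError("training data must contain both labels 0 and 1")
    coef_sum = np.zeros(4)
    for _ in range(reps):
        p = pos.sample(n=n_pos, replace=len(pos) < n_pos, random_state=rng)
        q = neg.sample(n=n_neg, replace=len(neg) < n_neg, random_state=rng)
        model = fit_reliability_model(pd.concat([p, q], ignore_index=True))
        coef_sum += model.coefficients
    return ReliabilityModel(*(coef_sum / reps))


def score_edge_reliability(
    model: ReliabilityModel, x: Mapping[str, float] | pd.Series
) -> float:
    """w = logistic(beta0 + beta1 x1 + beta2 x2 + beta3 x3), in (0, 1)."""
    eta = model.beta0 + model.beta1 * float(x["x1"]) + model.beta2 * float(
        x["x2"]
    ) + model.beta3 * float(x["x3"])
    return float(1.0 / (1.0 + np.exp(-eta)))


def score_edge_table(
    model: ReliabilityModel, features: pd.DataFrame
) -> pd.DataFrame:
    """Score every row; returns gene_a, gene_b, weight — a loadable edge list."""
    eta = _design(features) @ model.coefficients[1:] + model.beta0
    out = features.loc[:, ["gene_a", "gene_b"]].copy()
    out["weight"] = 1.0 / (1.0 + np.exp(-eta))
    return out


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """TSV gene_a, gene_b, x1, x2, x3[, label]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"gene_a", "gene_b", *FEATURES} - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return df
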