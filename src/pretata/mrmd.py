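"""Max-relevance max-distance (MRMD) feature ranking.

Each feature gets a relevance term — the absolute Pearson correlation between
the feature column and the binary class label — and a redundancy-resistance
term — its mean distance to every other feature column. The two are summed
with configurable weights (default 1, 1) and features are ranked by the sum,
so a feature scores high when it tracks the label and is far from (i.e. not
redundant with) the rest of the feature set.

Columns are min-max scaled to [0, 1] before the distance computation so that
relevance (in [0, 1] by construction) and distance are commensurable;
Euclidean distances are additionally divided by sqrt(n_rows), putting them in
[0, 1] as well. Cosine and Tanimoto distances are available as alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ctd import DomainError
from .seqio import FeatureTable

DISTANCE_FUNCTIONS = ("euclidean", "cosine", "tanimoto")


@dataclass
class RankedFeatures:
    """A permutation of feature indices with the scores behind it."""

    order: list[int]
    relevance: np.ndarray
    distance: np.ndarray
    score: np.ndarray
    feature_names: list[str]

    def top(self, d: int) -> list[int]:
        return self.order[:d]


def relevance(feature: np.ndarray, labels: np.ndarray) -> float:
    """|Pearson r| between a feature column and 0/1 labels; 0 if degenerate."""
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if feature.shape != labels.shape:
        raise DomainError("feature and labels must have equal length")
    if feature.size < 2:
        raise DomainError("need at least 2 rows")
    sf = feature.std()
    sl = labels.std()
    if sf == 0 or sl == 0:
        return 0.0
    r = np.mean((feature - feature.mean()) * (labels - labels.mean())) / (sf * sl)
    return float(abs(r))


def _minmax_columns(X: np.ndarray) -> np.ndarray:
    mins = X.min(axis=0)
    rng = X.max(axis=0) - mins
    out = np.full_like(X, 0.5, dtype=float)
    nz = rng > 0
    out[:, nz] = (X[:, nz] - mins[nz]) / rng[nz]
    return out


def _pairwise_distances(Xs: np.ndarray, distance: str) -> np.ndarray:
    n, p = Xs.shape
    if distance == "euclidean":
        sq = (Xs**2).sum(axis=0)
        d2 = sq[:, None] + sq[None, :] - 2 * Xs.T @ Xs
        np.clip(d2, 0, None, out=d2)
        return np.sqrt(d2) / np.sqrt(n)
    if distance == "cosine":
        norms = np.linalg.norm(Xs, axis=0)
        norms[norms == 0] = 1.0
        sim = (Xs.T @ Xs) / np.outer(norms, norms)
        return 1.0 - np.clip(sim, -1, 1)
    if distance == "tanimoto":
        dot = Xs.T @ Xs
        sq = np.diag(dot)
        denom = sq[:, None] + sq[None, :] - dot
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(denom > 0, dot / denom, 1.0)
        return 1.0 - sim
    raise ValueError(f"unknown distance {distance!r}")


def mean_feature_distance(
    index: int, table: FeatureTable, distance: str = "euclidean"
) -> float:
    """Mean distance from one feature column to every other column.

    Assumes the table has already been min-max scaled to [0, 1] (as
    :func:`mrmd_rank` does internally), so the normalized Euclidean distance
    lands in [0, 1].
    """
    if table.n_features < 2:
        raise DomainError("need at least 2 features for a distance term")
    D = _pairwise_distances(table.values, distance)
    p = table.n_features
    return float(D[index].sum() / (p - 1))


def mrmd_rank(
    table: FeatureTable,
    weights: tuple[float, float] = (1.0, 1.0),
    distance: str = "euclidean",
) -> RankedFeatures:
    """Rank all features by wr * relevance + wd * mean distance.

    Ties break toward the lower original feature index, so the ranking is a
    deterministic function of the table.
    """
    if table.labels is None:
        raise DomainError("MRMD ranking needs a labeled table")
    wr, wd = weights
    if wr < 0 or wd < 0:
        raise DomainError("weights must be non-negative")
    y = table.y()
    p = table.n_features
    rel = np.array([relevance(table.values[:, j], y) for j in range(p)])
    if p >= 2:
        D = _pairwise_distances(_minmax_columns(table.values), distance)
        dist = (D.sum(axis=1) - np.diag(D)) / (p - 1)
    else:
        dist = np.zeros(p)
    score = wr * rel + wd * dist
    order = sorted(range(p), key=lambda j: (-score[j], j))
    return RankedFeatures(
        order=order, relevance=rel, distance=dist, score=score,
        feature_names=list(table.feature_names),
    )


def ranking_to_rows(r: RankedFeatures) -> list[dict]:
    """Serializable per-feature rows (index, name, terms, rank)."""
    rank_of = {j: k for k, j in enumerate(r.order)}
    return [
        {
            "index": j,
            "name": r.feature_names[j],
            "relevance": float(r.relevance[j]),
            "distance": float(r.distance[j]),
            "score": float(r.score[j]),
            "rank": rank_of[j],
        }
        for j in range(len(r.feature_names))
    ]


def rows_to_ranking(rows: list[dict]) -> RankedFeatures:
    rows = sorted(rows, key=lambda r: r["index"])
    p = len(rows)
    order = [None] * p
    for r in rows:
        order[r["rank"]] = r["index"]
    return RankedFeatures(
        order=list(order),
        relevance=np.array([r["relevance"] for r in rows]),
        distance=np.array([r["distance"] for r in rows]),
        score=np.array([r["score"] for r in rows]),
        feature_names=[r["name"] for r in rows],
    )
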