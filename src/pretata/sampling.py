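"""Negative training-set construction from a large negative pool.

A protein classifier with a narrow positive class (here: TATA-binding
proteins) faces a negative pool that is much larger and more heterogeneous
than the positive set. This module implements four balancing strategies:

* :func:`random_undersample` — uniform draw without replacement.
* :func:`iterative_hard_negative_update` — repeatedly trains on the current
  negatives, predicts the held-out pool, and swaps pool negatives that the
  model misclassifies as positive ("hard" negatives, near the boundary) into
  the training set, stopping when cross-validated accuracy stops improving.
* :func:`sv_plus_set` — pools the negative-class support vectors over several
  random draws into a deduplicated high-quality negative set.
* :func:`distance_retention_resample` — keeps the fraction of the current
  negatives farthest (Euclidean) from the positive-class centroid and refills
  the rest from the pool, iterating until the pool can no longer supply a
  full refill.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ctd import DomainError
from .model import DEFAULT_C, DEFAULT_GAMMA, cross_validate, train
from .seqio import LABEL_NEGATIVE, LABEL_POSITIVE, FeatureTable, concat_rows


@dataclass
class SamplingConfig:
    n_negatives: int
    max_rounds: int = 10
    improvement_tol: float = 0.0  # ACC percentage points
    retain_fraction: float = 0.2
    cv_folds: int = 10
    c: float = DEFAULT_C
    gamma: float = DEFAULT_GAMMA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_negatives < 1:
            raise DomainError("n_negatives must be >= 1")
        if not (0.0 <= self.retain_fraction <= 1.0):
            raise DomainError("retain_fraction must be in [0, 1]")


def _as_labeled(pos: FeatureTable, neg: FeatureTable) -> FeatureTable:
    pos = FeatureTable(pos.row_ids, pos.feature_names, pos.values,
                       [LABEL_POSITIVE] * pos.n_rows)
    neg = FeatureTable(neg.row_ids, neg.feature_names, neg.values,
                       [LABEL_NEGATIVE] * neg.n_rows)
    return concat_rows(pos, neg)


def random_undersample(pool: FeatureTable, n: int, seed: int = 0) -> FeatureTable:
    """Uniform sample of n pool rows without replacement (seed-reproducible)."""
    if n > pool.n_rows:
        raise DomainError(f"cannot draw {n} rows from a pool of {pool.n_rows}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(pool.n_rows, size=n, replace=False)
    return pool.select_rows(sorted(int(i) for i in idx))


def _cv_acc(pos: FeatureTable, negs: FeatureTable, config: SamplingConfig) -> float:
    data = _as_labeled(pos, negs)
    folds = min(config.cv_folds, pos.n_rows, negs.n_rows)
    if folds < 2:
        raise DomainError("too few rows for cross-validation")
    return cross_validate(data, folds=folds, c=config.c, gamma=config.gamma,
                          seed=config.seed).acc


def iterative_hard_negative_update(
    pos: FeatureTable, pool: FeatureTable, config: SamplingConfig
) -> FeatureTable:
    """Refine a random negative set by swapping in misclassified pool negatives.

    Each round trains the SVM on positives + current negatives, predicts the
    rest of the pool, and replaces up to ``n_negatives // 2`` uniformly chosen
    incumbents with pool negatives the model calls positive. The loop stops
    when no pool negative is misclassified, when the round's CV accuracy fails
    to improve by more than ``improvement_tol``, or at ``max_rounds``.
    """
    if pos.n_rows == 0 or pool.n_rows == 0:
        raise DomainError("positive set and pool must be non-empty")
    if pool.n_rows < config.n_negatives:
        raise DomainError("pool smaller than n_negatives")
    rng = np.random.default_rng(config.seed)
    current = set(
        int(i) for i in rng.choice(pool.n_rows, size=config.n_negatives,
                                   replace=False)
    )
    if config.max_rounds <= 0:
        return pool.select_rows(sorted(current))
    acc = _cv_acc(pos, pool.select_rows(sorted(current)), config)
    for _ in range(config.max_rounds):
        negs = pool.select_rows(sorted(current))
        m = train(_as_labeled(pos, negs), c=config.c, gamma=config.gamma)
        held_out = sorted(set(range(pool.n_rows)) - current)
        if not held_out:
            break
        preds = m.predict(pool.select_rows(held_out))
        hard = [held_out[i] for i in np.flatnonzero(preds == 1)]
        if not hard:
            break
        k = min(len(hard), config.n_negatives // 2)
        swap_in = [int(i) for i in rng.choice(len(hard), size=k, replace=False)]
        incumbents = sorted(current)
        swap_out = rng.choice(len(incumbents), size=k, replace=False)
        new = set(current)
        for si, oi in zip(swap_in, swap_out):
            new.discard(incumbents[int(oi)])
            new.add(hard[si])
        new_acc = _cv_acc(pos, pool.select_rows(sorted(new)), config)
        current = new
        if new_acc - acc <= config.improvement_tol:
            break
        acc = new_acc
    return pool.select_rows(sorted(current))


def sv_plus_set(
    pos: FeatureTable, pool: FeatureTable, rounds: int, config: SamplingConfig
) -> FeatureTable:
    """Union of negative-class support vectors over repeated random draws.

    Each round draws ``n_negatives`` pool rows, fits the margin classifier on
    positives + draw, and keeps the draw's support vectors from the negative
    class. Rows are deduplicated by id across rounds.
    """
    if rounds < 1:
        raise DomainError("rounds must be >= 1")
    if pool.n_rows < config.n_negatives:
        raise DomainError("pool smaller than n_negatives")
    rng = np.random.default_rng(config.seed)
    kept_ids: dict[str, int] = {}
    for _ in range(rounds):
        idx = sorted(int(i) for i in
                     rng.choice(pool.n_rows, size=config.n_negatives,
                                replace=False))
        negs = pool.select_rows(idx)
        data = _as_labeled(pos, negs)
        m = train(data, c=config.c, gamma=config.gamma)
        sv_rows = m.negative_support_row_indices(data)
        for r in sv_rows:
            # negative rows sit after the positives in the stacked table
            pool_row = idx[int(r) - pos.n_rows]
            kept_ids.setdefault(pool.row_ids[pool_row], pool_row)
    return pool.select_rows(sorted(kept_ids.values()))


def distance_retention_resample(
    current_negs: FeatureTable,
    pool: FeatureTable,
    pos: FeatureTable,
    retain_fraction: float = 0.2,
    seed: int = 0,
    max_iterations: int | None = None,
) -> FeatureTable:
    """Keep the farthest negatives from the positive centroid; refill the rest.

    Each iteration retains the ``retain_fraction`` of the current negatives
    with the largest Euclidean distance to the positive-class centroid and
    draws the remainder from the pool without replacement; iteration stops
    when the pool cannot supply a full refill (or at ``max_iterations``).
    """
    if not (0.0 <= retain_fraction <= 1.0):
        raise DomainError("retain_fraction must be in [0, 1]")
    n = current_negs.n_rows
    n_keep = int(round(retain_fraction * n))
    n_refill = n - n_keep
    if retain_fraction == 1.0 or n_refill == 0:
        return current_negs
    rng = np.random.default_rng(seed)
    centroid = pos.values.mean(axis=0)
    available = list(range(pool.n_rows))
    if len(available) < n_refill:
        raise DomainError(
            f"pool ({len(available)}) cannot supply the first refill of {n_refill}"
        )
    cur = current_negs
    it = 0
    while len(available) >= n_refill:
        if max_iterations is not None and it >= max_iterations:
            break
        dists = np.linalg.norm(cur.values - centroid, axis=1)
        keep_idx = list(np.argsort(-dists, kind="stable")[:n_keep])
        kept = cur.select_rows(sorted(int(i) for i in keep_idx))
        draw = rng.choice(len(available), size=n_refill, replace=False)
        draw_rows = sorted(available[int(i)] for i in draw)
        fresh = pool.select_rows(draw_rows)
        available = [a for a in available if a not in set(draw_rows)]
        cur = FeatureTable(
            row_ids=kept.row_ids + fresh.row_ids,
            feature_names=list(cur.feature_names),
            values=np.vstack([kept.values, fresh.values]),
            labels=None,
        )
        it += 1
    return cur
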