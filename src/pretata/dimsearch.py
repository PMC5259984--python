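"""Two-step search for the optimal number of ranked features.

Given an MRMD ranking, the classifier is cross-validated on the top-d feature
prefixes. A coarse primary pass steps down from the initial dimensionality in
large decrements (default 20) to a tolerable floor; a fine secondary pass then
scans a window around the coarse optimum (default +/-50) in small steps
(default 2). The reported best is the accuracy argmax over both traces, with
ties resolved toward the smaller dimensionality (the cheaper model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ctd import DomainError
from .mrmd import RankedFeatures
from .model import DEFAULT_C, DEFAULT_FOLDS, DEFAULT_GAMMA, cross_validate
from .seqio import FeatureTable


@dataclass
class SearchConfig:
    initial_dim: int
    tolerable_dim: int
    primary_step: int = 20
    secondary_step: int = 2
    window_halfwidth: int = 50
    cv_folds: int = DEFAULT_FOLDS
    c: float = DEFAULT_C
    gamma: float = DEFAULT_GAMMA
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.tolerable_dim <= self.initial_dim):
            raise DomainError(
                f"need 1 <= tolerable_dim <= initial_dim, got "
                f"{self.tolerable_dim}..{self.initial_dim}"
            )
        if self.primary_step < 1 or self.secondary_step < 1:
            raise DomainError("steps must be >= 1")


@dataclass
class SearchResult:
    """Evaluation trace and the best (dimension, SN, SP, ACC) found."""

    evaluated: list[tuple[int, float, float, float]]  # (d, SN, SP, ACC)
    best_dimension: int
    best_metrics: tuple[float, float, float]
    phase: str  # "primary" or "secondary"


def evaluate_prefix(
    table: FeatureTable,
    ranking: RankedFeatures,
    d: int,
    folds: int = DEFAULT_FOLDS,
    c: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
    seed: int = 0,
) -> tuple[float, float, float]:
    """(SN, SP, ACC) of k-fold CV on the top-d ranked features."""
    if not (1 <= d <= table.n_features):
        raise DomainError(f"prefix size {d} out of range 1..{table.n_features}")
    sub = table.select_features(ranking.top(d))
    m = cross_validate(sub, folds=folds, c=c, gamma=gamma, seed=seed)
    return m.sn, m.sp, m.acc


def _best_of(evaluated) -> tuple[int, tuple[float, float, float]]:
    # argmax ACC; ties -> smaller dimension
    best_d, best_m = None, None
    for d, sn, sp, acc in sorted(evaluated):
        if best_m is None or acc > best_m[2]:
            best_d, best_m = d, (sn, sp, acc)
    return best_d, best_m


def primary_search(
    table: FeatureTable, ranking: RankedFeatures, config: SearchConfig
) -> SearchResult:
    """Coarse pass: initial_dim, initial_dim - step, ... down to the floor."""
    dims = list(range(config.initial_dim, config.tolerable_dim - 1,
                      -config.primary_step))
    evaluated = []
    for d in dims:
        sn, sp, acc = evaluate_prefix(
            table, ranking, d, folds=config.cv_folds,
            c=config.c, gamma=config.gamma, seed=config.seed,
        )
        evaluated.append((d, sn, sp, acc))
    best_d, best_m = _best_of(evaluated)
    return SearchResult(
        evaluated=evaluated, best_dimension=best_d,
        best_metrics=best_m, phase="primary",
    )


def two_step_search(
    table: FeatureTable, ranking: RankedFeatures, config: SearchConfig
) -> tuple[SearchResult, SearchResult, SearchResult]:
    """Coarse pass, then a fine scan around the coarse optimum.

    Returns (primary_result, secondary_result, combined_result); the combined
    result's trace is the union of both phases and its best is the overall
    argmax (ties toward smaller dimensionality). The fine grid always contains
    the coarse optimum, so the combined best ACC never falls below the coarse
    best.
    """
    primary = primary_search(table, ranking, config)
    lo = max(config.tolerable_dim, primary.best_dimension - config.window_halfwidth)
    hi = min(config.initial_dim, primary.best_dimension + config.window_halfwidth)
    fine_dims = sorted(set(range(lo, hi + 1, config.secondary_step))
                       | {primary.best_dimension})
    already = {d: (sn, sp, acc) for d, sn, sp, acc in primary.evaluated}
    fine_eval = []
    for d in fine_dims:
        if d in already:
            sn, sp, acc = already[d]
        else:
            sn, sp, acc = evaluate_prefix(
                table, ranking, d, folds=config.cv_folds,
                c=config.c, gamma=config.gamma, seed=config.seed,
            )
        fine_eval.append((d, sn, sp, acc))
    sec_d, sec_m = _best_of(fine_eval)
    secondary = SearchResult(
        evaluated=fine_eval, best_dimension=sec_d,
        best_metrics=sec_m, phase="secondary",
    )
    union = {(d,): (d, sn, sp, acc) for d, sn, sp, acc in
             primary.evaluated + fine_eval}
    combined_eval = sorted(union.values())
    comb_d, comb_m = _best_of(combined_eval)
    phase = "secondary" if (comb_d, comb_m) == (sec_d, sec_m) else "primary"
    combined = SearchResult(
        evaluated=combined_eval, best_dimension=comb_d,
        best_metrics=comb_m, phase=phase,
    )
    return primary, secondary, combined


def trace_rows(result: SearchResult) -> list[dict]:
    return [
        {"dimension": d, "SN": sn, "SP": sp, "ACC": acc}
        for d, sn, sp, acc in result.evaluated
    ]
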