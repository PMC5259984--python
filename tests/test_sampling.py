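import numpy as np
import pytest

from pretata.ctd import DomainError
from pretata.model import train
from pretata.sampling import (
    SamplingConfig,
    _as_labeled,
    distance_retention_resample,
    iterative_hard_negative_update,
    random_undersample,
    sv_plus_set,
)
from pretata.seqio import FeatureTable
from pretata.synthetic import generate_hard_negative_pool


@pytest.fixture(scope="module")
def planted():
    return generate_hard_negative_pool(
        n_pos=60, n_pool=240, n_boundary=24, seed=17
    )


class TestRandomUndersample:
    def test_exhaustive_sample_is_whole_pool(self, planted):
        _pos, pool, _mask = planted
        out = random_undersample(pool, pool.n_rows, seed=0)
        assert sorted(out.row_ids) == sorted(pool.row_ids)

    def test_same_seed_identical_subset(self, planted):
        _pos, pool, _mask = planted
        a = random_undersample(pool, 50, seed=4)
        b = random_undersample(pool, 50, seed=4)
        assert a.row_ids == b.row_ids

    def test_oversized_draw_rejected(self, planted):
        _pos, pool, _mask = planted
        with pytest.raises(DomainError):
            random_undersample(pool, pool.n_rows + 1)

    def test_single_draws_are_uniform(self):
        pool = FeatureTable(row_ids=["a", "b"], feature_names=["f"],
                            values=np.array([[0.0], [1.0]]))
        hits = sum(random_undersample(pool, 1, seed=s).row_ids == ["a"]
                   for s in range(10_000))
        # Binomial(10000, 1/2): 5000 +/- 200 covers ~99.99%
        assert 4800 <= hits <= 5200


class TestIterativeHardNegativeUpdate:
    def test_planted_boundary_negatives_enriched(self, planted):
        pos, pool, mask = planted
        cfg = SamplingConfig(n_negatives=60, max_rounds=8, seed=17)
        out = iterative_hard_negative_update(pos, pool, cfg)
        assert out.n_rows == 60
        boundary_ids = {pool.row_ids[i] for i in np.flatnonzero(mask)}
        frac = sum(r in boundary_ids for r in out.row_ids) / out.n_rows
        assert frac >= 2 * mask.mean()

    def test_separated_pool_is_fixed_point(self):
        pos, pool, _mask = generate_hard_negative_pool(
            n_pos=40, n_pool=120, n_boundary=0, separation=8.0, seed=3
        )
        cfg = SamplingConfig(n_negatives=40, max_rounds=5, seed=3)
        out = iterative_hard_negative_update(pos, pool, cfg)
        initial = random_undersample(pool, 40, seed=3)
        # no pool negative is misclassified, so round 1 keeps the initial draw
        assert sorted(out.row_ids) == sorted(initial.row_ids)

    def test_zero_rounds_returns_initial_random_set(self, planted):
        pos, pool, _mask = planted
        cfg = SamplingConfig(n_negatives=50, max_rounds=0, seed=9)
        out = iterative_hard_negative_update(pos, pool, cfg)
        initial = random_undersample(pool, 50, seed=9)
        assert sorted(out.row_ids) == sorted(initial.row_ids)

    def test_output_is_pool_subset_of_requested_size(self, planted):
        pos, pool, _mask = planted
        cfg = SamplingConfig(n_negatives=45, max_rounds=4, seed=2)
        out = iterative_hard_negative_update(pos, pool, cfg)
        assert out.n_rows == 45
        assert set(out.row_ids) <= set(pool.row_ids)

    def test_refinement_does_not_degrade_on_well_spread_pool(self):
        # With a well-spread negative pool the refinement loop finds nothing
        # to swap and must not end up below the initial random draw.
        from pretata.sampling import _cv_acc
        pos, pool, _mask = generate_hard_negative_pool(
            n_pos=50, n_pool=200, n_boundary=0, separation=6.0, seed=23
        )
        cfg = SamplingConfig(n_negatives=50, max_rounds=8, seed=23)
        refined = iterative_hard_negative_update(pos, pool, cfg)
        initial = random_undersample(pool, 50, seed=23)
        acc_refined = _cv_acc(pos, refined, cfg)
        acc_initial = _cv_acc(pos, initial, cfg)
        assert acc_refined >= acc_initial - cfg.improvement_tol - 1e-9


class TestSvPlusSet:
    def test_single_round_equals_negative_support_vectors(self, planted):
        pos, pool, _mask = planted
        cfg = SamplingConfig(n_negatives=60, seed=5)
        plus = sv_plus_set(pos, pool, rounds=1, config=cfg)
        negs = random_undersample(pool, 60, seed=5)
        data = _as_labeled(pos, negs)
        m = train(data)
        sv_ids = {data.row_ids[i]
                  for i in m.negative_support_row_indices(data)}
        assert set(plus.row_ids) == sv_ids

    def test_wide_margin_keeps_few_vectors(self):
        pos, pool, _mask = generate_hard_negative_pool(
            n_pos=40, n_pool=200, n_boundary=0, separation=8.0, seed=7
        )
        cfg = SamplingConfig(n_negatives=40, seed=7)
        plus = sv_plus_set(pos, pool, rounds=5, config=cfg)
        assert plus.n_rows < 0.25 * 40 * 5

    def test_ids_deduplicated_across_rounds(self, planted):
        pos, pool, _mask = planted
        cfg = SamplingConfig(n_negatives=120, seed=1)  # draws must overlap
        plus = sv_plus_set(pos, pool, rounds=6, config=cfg)
        assert len(plus.row_ids) == len(set(plus.row_ids))

    def test_zero_rounds_rejected(self, planted):
        pos, pool, _mask = planted
        with pytest.raises(DomainError):
            sv_plus_set(pos, pool, rounds=0,
                        config=SamplingConfig(n_negatives=10))


class TestDistanceRetention:
    def test_full_retention_is_identity(self, planted):
        pos, pool, _mask = planted
        current = random_undersample(pool, 40, seed=0)
        out = distance_retention_resample(current, pool, pos,
                                          retain_fraction=1.0)
        assert out.row_ids == current.row_ids

    def test_zero_retention_draws_fresh_rows(self, planted):
        pos, pool, _mask = planted
        current = random_undersample(pool, 40, seed=0)
        out = distance_retention_resample(current, pool, pos,
                                          retain_fraction=0.0, seed=1,
                                          max_iterations=1)
        assert out.n_rows == 40
        assert set(out.row_ids) <= set(pool.row_ids)

    def test_retained_rows_are_farthest_by_sort_oracle(self, planted):
        pos, pool, _mask = planted
        current = random_undersample(pool, 40, seed=0)
        centroid = pos.values.mean(axis=0)
        dists = np.linalg.norm(current.values - centroid, axis=1)
        expected = {current.row_ids[i]
                    for i in np.argsort(-dists, kind="stable")[:8]}
        out = distance_retention_resample(current, pool, pos,
                                          retain_fraction=0.2, seed=2,
                                          max_iterations=1)
        assert expected <= set(out.row_ids)
        assert out.n_rows == 40

    def test_insufficient_pool_rejected(self, planted):
        pos, pool, _mask = planted
        current = random_undersample(pool, 40, seed=0)
        tiny_pool = pool.select_rows(range(10))
        with pytest.raises(DomainError, match="refill"):
            distance_retention_resample(current, tiny_pool, pos,
                                        retain_fraction=0.2)
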