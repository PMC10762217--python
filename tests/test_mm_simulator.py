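import logging

import numpy as np
import pytest

from pxmdc import (
    MCAR,
    MNAR,
    MissingnessSpec,
    ThresholdParams,
    simulate_mm,
    tier_by_mean_rule,
    tier_by_percent,
)
from pxmdc.mm_simulator import HIGH, LOW, MEDIUM

from conftest import make_complete


class TestTierByPercent:
    def test_all_high_at_x100(self):
        mat = make_complete(np.arange(1, 13).reshape(4, 3))
        tiers = tier_by_percent(mat, ThresholdParams(100, 0, 0, 0.5))
        assert set(tiers.tiers) == {HIGH}

    def test_rank_partition_on_four_metabolites(self):
        mat = make_complete([[10, 10], [8, 8], [2, 2], [1, 1]])
        tiers = tier_by_percent(mat, ThresholdParams(25, 50, 25, 0.5))
        assert tiers.tiers.tolist() == [HIGH, MEDIUM, MEDIUM, LOW]

    def test_round_half_up_counts(self):
        mat = make_complete(np.arange(1, 21).reshape(10, 2)[::-1])
        tiers = tier_by_percent(mat, ThresholdParams(33, 33, 34, 0.5))
        counts = tiers.counts()
        assert (counts[HIGH], counts[MEDIUM], counts[LOW]) == (3, 3, 4)

    def test_ties_broken_by_metabolite_id(self):
        # equal means: ranking falls back to lexicographic metabolite id
        mat = make_complete([[5, 5], [5, 5], [5, 5], [5, 5]])
        tiers = tier_by_percent(mat, ThresholdParams(50, 0, 50, 0.5))
        assert tiers.tiers.tolist() == [HIGH, HIGH, LOW, LOW]


class TestTierByMeanRule:
    def test_rule_application_and_strict_boundaries(self):
        # grand mean g = (6 + 4 + 2 + 0.3) / 4 = 3.075; cutoffs g and g/10
        mat = make_complete([[6, 6], [4, 4], [2, 2], [0.3, 0.3]])
        tiers = tier_by_mean_rule(mat)
        assert tiers.tiers.tolist() == [HIGH, HIGH, MEDIUM, LOW]

    def test_mean_exactly_at_boundary_is_medium(self):
        mat = make_complete([[6, 6], [2, 2]])  # g = 4; neither mean is > 4 except row 0
        tiers = tier_by_mean_rule(mat)
        assert tiers.tiers.tolist() == [HIGH, MEDIUM]
        same = make_complete([[4, 4], [4, 4]])  # every mean equals g exactly
        assert tier_by_mean_rule(same).tiers.tolist() == [MEDIUM, MEDIUM]


class TestSimulateMM:
    def _four_by_four(self):
        values = [
            [100, 110, 90, 105],
            [50, 55, 45, 52],
            [30, 35, 25, 32],
            [1, 4, 2, 3],
        ]
        return make_complete(values)

    def test_zero_rate_returns_unmasked_copy(self):
        mat = self._four_by_four()
        params = ThresholdParams(25, 50, 25, 0.5)
        out = simulate_mm(
            mat, tier_by_percent(mat, params),
            MissingnessSpec(rate=0.0, params=params, seed=0),
        )
        assert out.n_missing == 0
        assert out.labels == {}

    def test_alpha_zero_gives_only_mcar(self):
        mat = self._four_by_four()
        params = ThresholdParams(25, 50, 25, 0.0)
        out = simulate_mm(
            mat, tier_by_percent(mat, params),
            MissingnessSpec(rate=0.1, params=params, seed=0),
        )
        assert out.n_missing == 2  # round(0.1 * 16)
        assert set(out.labels.values()) == {MCAR}

    def test_mnar_is_two_smallest_low_tier_cells(self):
        # one LOW metabolite (row 3), k = 4, alpha = 0.5 -> MNAR = its 2 smallest
        mat = self._four_by_four()
        params = ThresholdParams(25, 50, 25, 0.5)
        out = simulate_mm(
            mat, tier_by_percent(mat, params),
            MissingnessSpec(rate=0.25, params=params, seed=7),
        )
        mnar_cells = {c for c, mech in out.labels.items() if mech == MNAR}
        assert mnar_cells == {(3, 0), (3, 2)}  # values 1 and 2
        assert sum(1 for mech in out.labels.values() if mech == MCAR) == 2

    def test_capacity_capping_reassigns_to_mcar(self, caplog):
        mat = self._four_by_four()
        params = ThresholdParams(25, 50, 25, 1.0)  # wants 8 MNAR, capacity 4
        with caplog.at_level(logging.WARNING):
            out = simulate_mm(
                mat, tier_by_percent(mat, params),
                MissingnessSpec(rate=0.5, params=params, seed=1),
            )
        assert out.n_missing == 8
        n_mnar = sum(1 for mech in out.labels.values() if mech == MNAR)
        assert n_mnar == 4  # all LOW-tier cells
        assert any("reassigned" in rec.message for rec in caplog.records)

    def test_deterministic_under_seed(self, fixture_matrix):
        params = ThresholdParams(30, 40, 30, 0.5)
        tiers = tier_by_percent(fixture_matrix, params)
        spec = MissingnessSpec(rate=0.2, params=params, seed=5)
        a = simulate_mm(fixture_matrix, tiers, spec)
        b = simulate_mm(fixture_matrix, tiers, spec)
        np.testing.assert_array_equal(a.mask, b.mask)
        assert a.labels == b.labels


@pytest.mark.parametrize("seed", range(20))
def test_mm_invariants_random_configs(seed):
    """Conservation, mechanism partition, LOW confinement, left-censoring."""
    rng = np.random.default_rng(seed)
    m, n = int(rng.integers(5, 25)), int(rng.integers(4, 15))
    x = float(rng.integers(0, 101))
    y = float(rng.integers(0, int(101 - x)))
    params = ThresholdParams(x, y, 100 - x - y, float(rng.uniform(0, 1)))
    rate = float(rng.uniform(0, 0.4))
    values = rng.lognormal(mean=rng.uniform(0, 5, size=(m, 1)), sigma=0.3, size=(m, n))
    mat = make_complete(values)
    tiers = tier_by_percent(mat, params)
    out = simulate_mm(mat, tiers, MissingnessSpec(rate=rate, params=params, seed=seed))

    k = int(np.floor(rate * m * n + 0.5))
    assert out.n_missing == k
    assert set(out.labels) == {tuple(c) for c in np.argwhere(out.mask)}
    low_rows = set(np.nonzero(tiers.low_mask)[0])
    mnar = [c for c, mech in out.labels.items() if mech == MNAR]
    assert all(i in low_rows for i, _ in mnar)
    if mnar and low_rows:
        mnar_max = max(mat.values[i, j] for i, j in mnar)
        retained = [
            mat.values[i, j]
            for i in low_rows
            for j in range(n)
            if not out.mask[i, j]
        ]
        if retained:
            assert mnar_max <= min(retained)


def test_realized_mnar_share_matches_alpha_across_seeds(fixture_matrix):
    params = ThresholdParams(20, 30, 50, 0.45)
    tiers = tier_by_percent(fixture_matrix, params)
    fracs = []
    for seed in range(10):
        out = simulate_mm(
            fixture_matrix, tiers, MissingnessSpec(rate=0.1, params=params, seed=seed)
        )
        n_mnar = sum(1 for mech in out.labels.values() if mech == MNAR)
        fracs.append(n_mnar / out.n_missing)
    # share is set by rounding, not sampling: tight agreement expected
    assert abs(np.mean(fracs) - 0.45) < 0.01


def test_mean_rule_tiers_also_drive_simulation(fixture_matrix):
    tiers = tier_by_mean_rule(fixture_matrix)
    params = ThresholdParams(0, 0, 100, 0.6)
    out = simulate_mm(
        fixture_matrix, tiers, MissingnessSpec(rate=0.1, params=params, seed=3)
    )
    mnar_rows = {i for (i, _), mech in out.labels.items() if mech == MNAR}
    assert mnar_rows <= set(np.nonzero(tiers.low_mask)[0])
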