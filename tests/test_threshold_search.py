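import numpy as np
import pytest

from pxmdc import (
    MissingnessSpec,
    PSOConfig,
    SyntheticSpec,
    ThresholdParams,
    enumerate_search,
    generate_complete_matrix,
    missing_rate_vector,
    objective,
    percentage_difference,
    pso_search,
    replicate_seed,
    simulate_mm,
    tier_by_percent,
    vector_distance,
)

from conftest import make_masked


def small_instance(seed=0, m=20, n=10):
    return generate_complete_matrix(
        SyntheticSpec(m=m, n=n, log_mean_range=(0, 3), within_metabolite_cv=0.25, seed=seed)
    )


class TestMissingRateVector:
    def test_complete_matrix_gives_zero_vector(self):
        mat = make_masked(np.ones((3, 4)), np.zeros((3, 4), dtype=bool))
        np.testing.assert_array_equal(missing_rate_vector(mat), np.zeros(3))

    def test_half_missing_row(self):
        mask = np.array([[True, True, False, False]])
        mat = make_masked(np.where(mask, np.nan, 1.0), mask)
        assert missing_rate_vector(mat)[0] == 0.5

    def test_all_missing_gives_ones(self):
        mat = make_masked(np.full((2, 3), np.nan), np.ones((2, 3), dtype=bool))
        np.testing.assert_array_equal(missing_rate_vector(mat), np.ones(2))

    def test_ordered_by_metabolite_id(self):
        from pxmdc import MaskedMatrix

        mat = MaskedMatrix(
            metabolite_ids=["zzz", "aaa"],
            sample_ids=["s1", "s2"],
            values=np.array([[np.nan, np.nan], [1.0, 2.0]]),
            mask=np.array([[True, True], [False, False]]),
        )
        np.testing.assert_array_equal(missing_rate_vector(mat), [0.0, 1.0])


class TestVectorDistance:
    def test_identity_symmetry_and_pythagoras(self):
        a, b = np.array([0.0, 0.0]), np.array([0.3, 0.4])
        assert vector_distance(a, a) == 0.0
        assert vector_distance(a, b) == pytest.approx(0.5)
        rng = np.random.default_rng(0)
        u, v = rng.uniform(size=8), rng.uniform(size=8)
        assert vector_distance(u, v) == pytest.approx(vector_distance(v, u))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            vector_distance(np.zeros(3), np.zeros(4))


class TestObjective:
    def test_self_distance_is_zero_with_shared_seed_stream(self):
        mat = small_instance(seed=3)
        params = ThresholdParams(20, 50, 30, 0.5)
        tiers = tier_by_percent(mat, params)
        seed = 7
        drawn = simulate_mm(
            mat, tiers,
            MissingnessSpec(rate=0.2, params=params, seed=replicate_seed(seed, 0)),
        )
        target = missing_rate_vector(drawn)
        assert objective(params, mat, target, 0.2, n_rep=1, seed=seed) == 0.0

    def test_zero_rate_with_zero_target_is_zero(self):
        mat = small_instance(seed=3)
        value = objective(
            ThresholdParams(10, 20, 70, 0.3), mat, np.zeros(20), 0.0, n_rep=3, seed=0
        )
        assert value == 0.0

    def test_replicate_averaging_reduces_seed_variance(self):
        mat = small_instance(seed=4)
        params = ThresholdParams(20, 50, 30, 0.5)
        tiers = tier_by_percent(mat, params)
        truth = simulate_mm(mat, tiers, MissingnessSpec(rate=0.2, params=params, seed=999))
        target = missing_rate_vector(truth)
        one = [objective(params, mat, target, 0.2, n_rep=1, seed=s) for s in range(30)]
        ten = [objective(params, mat, target, 0.2, n_rep=10, seed=s) for s in range(30)]
        assert np.var(ten) < np.var(one)
        assert min(one + ten) >= 0.0


class TestPSO:
    def test_sphere_function_minimum_recovered(self):
        sphere = lambda p: (p.x - 30) ** 2 + (p.y - 40) ** 2 + (100 * (p.alpha - 0.5)) ** 2
        res = pso_search(None, None, 0.0, PSOConfig(seed=2), _objective=sphere)
        assert res.best.x == pytest.approx(30, abs=1e-3)
        assert res.best.y == pytest.approx(40, abs=1e-3)
        assert res.best.alpha == pytest.approx(0.5, abs=1e-5)

    def test_deterministic_under_seed(self):
        mat = small_instance(seed=5)
        params = ThresholdParams(0, 0, 100, 0.4)
        tiers = tier_by_percent(mat, params)
        truth = simulate_mm(mat, tiers, MissingnessSpec(rate=0.2, params=params, seed=1))
        target = missing_rate_vector(truth)
        cfg = PSOConfig(swarm_size=10, max_iter=20, n_rep=3, seed=9)
        a = pso_search(mat, target, 0.2, cfg)
        b = pso_search(mat, target, 0.2, cfg)
        assert a.best == b.best
        assert a.objective == b.objective
        assert a.trace == b.trace

    def test_trace_monotone_and_never_worse_than_initial(self):
        mat = small_instance(seed=6)
        target = np.zeros(20)
        res = pso_search(mat, target, 0.1, PSOConfig(swarm_size=8, max_iter=15, n_rep=2, seed=0))
        assert all(b <= a for a, b in zip(res.trace, res.trace[1:]))
        assert res.objective <= res.trace[0]


class TestEnumeration:
    def test_step_fifty_grid_has_twelve_points(self):
        mat = small_instance(seed=1)
        res = enumerate_search(mat, np.zeros(20), 0.1, step=50, n_rep=2, seed=0)
        assert res.evaluations == 12

    def test_minimum_not_above_any_probed_grid_point(self):
        mat = small_instance(seed=2)
        params = ThresholdParams(0, 0, 100, 0.5)
        tiers = tier_by_percent(mat, params)
        truth = simulate_mm(mat, tiers, MissingnessSpec(rate=0.2, params=params, seed=0))
        target = missing_rate_vector(truth)
        res = enumerate_search(mat, target, 0.2, step=25, n_rep=3, seed=11)
        for x in range(0, 101, 25):
            for y in range(0, 101 - x, 25):
                for a_pct in range(25, 101, 25):
                    p = ThresholdParams(x, y, 100 - x - y, a_pct / 100)
                    assert res.objective <= objective(p, mat, target, 0.2, n_rep=3, seed=11) + 1e-12

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            enumerate_search(small_instance(), np.zeros(20), 0.1, step=3)


def test_pso_matches_coarse_enumeration_oracle():
    mat = small_instance(seed=8)
    gen = ThresholdParams(25, 45, 30, 0.5)
    tiers = tier_by_percent(mat, gen)
    truth = simulate_mm(mat, tiers, MissingnessSpec(rate=0.2, params=gen, seed=123))
    target = missing_rate_vector(truth)
    seed = 17
    pso = pso_search(mat, target, 0.2, PSOConfig(n_rep=10, seed=seed))
    enum = enumerate_search(mat, target, 0.2, step=5, n_rep=10, seed=seed)
    assert pso.objective <= enum.objective + 1e-9
    assert abs(pso.best.alpha - enum.best.alpha) <= 0.05


def test_mnar_share_recovered_from_known_generator(fixture_matrix):
    """The MNAR share alpha is the identifiable part of the generator: targets
    built at known alpha* are recovered within 0.05 by the swarm.

    The x/y tier split (and any LOW share beyond the censored metabolites) leaves
    the missing-rate vector unchanged, so only alpha is asserted here.
    """
    gen = ThresholdParams(30, 40, 30, 0.5)
    tiers = tier_by_percent(fixture_matrix, gen)
    for seed in range(5):
        truth = simulate_mm(
            fixture_matrix, tiers, MissingnessSpec(rate=0.1, params=gen, seed=300 + seed)
        )
        target = missing_rate_vector(truth)
        res = pso_search(fixture_matrix, target, 0.1, PSOConfig(n_rep=10, seed=seed))
        assert abs(res.best.alpha - 0.5) <= 0.05


def test_percentage_difference_convention():
    a = ThresholdParams(50, 25, 25, 0.5)
    b = ThresholdParams(40, 35, 25, 0.55)
    diff = percentage_difference(a, b)
    assert diff["x"] == pytest.approx(0.2)
    assert diff["z"] == 0.0
    assert diff["alpha"] == pytest.approx(0.1)
    zero = ThresholdParams(0, 50, 50, 0.5)
    assert percentage_difference(zero, zero)["x"] == 0.0
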