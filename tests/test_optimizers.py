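import numpy as np
import pytest

from cultivopt.optimizers import (
    BBOConfig,
    GAConfig,
    ISAConfig,
    OptimizerError,
    Problem,
    SOSConfig,
    best_f_spread,
    default_configs,
    isa_alpha,
    optimize_all,
    optimize_bbo,
    optimize_ga,
    optimize_isa,
    optimize_sos,
    results_table,
)

BOUNDS5 = np.array([[0.0, 1.0]] * 5)

ALGOS = [
    (optimize_ga, GAConfig),
    (optimize_bbo, BBOConfig),
    (optimize_isa, ISAConfig),
    (optimize_sos, SOSConfig),
]


def sphere_problem(center=0.3):
    return Problem(lambda X: -np.sum((X - center) ** 2, axis=1), BOUNDS5)


def _small(cfg_cls, seed=3):
    return cfg_cls(population=40, generations=120, seed=seed)


class TestSharedContract:
    @pytest.mark.parametrize("fn,cfg_cls", ALGOS)
    def test_sphere_optimum_recovered(self, fn, cfg_cls):
        r = fn(sphere_problem(), _small(cfg_cls))
        assert np.abs(r.best_x - 0.3).max() < 2e-2
        assert r.best_f > -1e-3

    @pytest.mark.parametrize("fn,cfg_cls", ALGOS)
    def test_incumbent_history_monotone(self, fn, cfg_cls):
        r = fn(sphere_problem(), _small(cfg_cls))
        assert (np.diff(r.history) >= 0).all()

    @pytest.mark.parametrize("fn,cfg_cls", ALGOS)
    def test_every_candidate_within_bounds(self, fn, cfg_cls):
        seen = []

        def objective(X):
            seen.append(X.copy())
            return -np.sum((X - 0.3) ** 2, axis=1)

        fn(Problem(objective, BOUNDS5), _small(cfg_cls))
        allx = np.vstack(seen)
        assert (allx >= 0.0).all() and (allx <= 1.0).all()

    @pytest.mark.parametrize("fn,cfg_cls", ALGOS)
    def test_same_seed_bit_identical(self, fn, cfg_cls):
        a = fn(sphere_problem(), _small(cfg_cls, seed=9))
        b = fn(sphere_problem(), _small(cfg_cls, seed=9))
        assert np.array_equal(a.best_x, b.best_x)
        assert a.best_f == b.best_f
        assert np.array_equal(a.history, b.history)

    @pytest.mark.parametrize("fn,cfg_cls", ALGOS)
    def test_non_finite_objective_reports_point(self, fn, cfg_cls):
        bad = Problem(lambda X: np.full(len(X), np.nan), BOUNDS5)
        with pytest.raises(OptimizerError, match="non-finite"):
            fn(bad, _small(cfg_cls))

    def test_population_of_one_rejected(self):
        with pytest.raises(OptimizerError, match="population"):
            optimize_ga(sphere_problem(), GAConfig(population=1))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(OptimizerError):
            Problem(lambda X: X.sum(axis=1), np.array([[1.0, 0.0]]))


class TestGA:
    def test_one_dimensional_two_bump_matches_grid_oracle(self):
        def f(X):
            x = X[:, 0]
            return np.exp(-((x - 0.2) ** 2) / 0.002) + 1.4 * np.exp(
                -((x - 0.8) ** 2) / 0.003
            )

        grid = np.linspace(0, 1, 10_001)[:, None]  # 1e-4 resolution
        f_opt = f(grid).max()
        r = optimize_ga(
            Problem(f, np.array([[0.0, 1.0]])),
            GAConfig(population=200, generations=300, seed=0),
        )
        assert r.best_f == pytest.approx(f_opt, abs=1e-4)


class TestBBO:
    def test_zero_alpha_migration_is_a_no_op(self):
        # with α=0 and no mutation the population can never move, so the
        # incumbent stays at the best initial habitat
        prob = sphere_problem()
        cfg = BBOConfig(population=30, generations=50, seed=2, alpha=0.0, mutation_rate=0.0)
        r = optimize_bbo(prob, cfg)
        rng = np.random.default_rng(2)
        init = rng.random((30, 5))
        assert r.best_f == pytest.approx(float(prob.objective(init).max()))

    def test_as_printed_migration_stays_within_bounds(self):
        # archaeology flag: the uncorrected plus-sign update still respects
        # the clipping contract even though it pushes iterates to the walls
        r = optimize_bbo(
            sphere_problem(),
            BBOConfig(population=30, generations=30, seed=0, as_printed=True),
        )
        assert (r.best_x >= 0).all() and (r.best_x <= 1).all()


class TestISA:
    def test_alpha_schedule_endpoints(self):
        assert isa_alpha(0, 100) == pytest.approx(0.1)
        assert isa_alpha(99, 100) == pytest.approx(0.9)
        assert isa_alpha(0, 1) == pytest.approx(0.9)


class TestSOS:
    def test_population_fitness_never_decreases(self):
        # greedy acceptance in every phase: track the population best via
        # the incumbent history
        r = optimize_sos(sphere_problem(), SOSConfig(population=20, generations=30, seed=1))
        assert (np.diff(r.history) >= 0).all()


class TestRunner:
    def test_all_four_algorithms_reported(self):
        res = optimize_all(sphere_problem(), default_configs(30, 60, seed=4))
        assert set(res) == {"ga", "bbo", "isa", "sos"}
        table = results_table(res, ("a", "b", "c", "d", "e"), trait="t")
        assert len(table) == 4
        assert set(table["algorithm"]) == {"ga", "bbo", "isa", "sos"}

    def test_agreement_on_smooth_unimodal_objective(self):
        prob = Problem(lambda X: 10.0 - np.sum((X - 0.4) ** 2, axis=1), BOUNDS5)
        res = optimize_all(prob, default_configs(50, 150, seed=4))
        assert best_f_spread(res) < 1e-3

    def test_reproducible_table(self):
        a = optimize_all(sphere_problem(), default_configs(20, 40, seed=5))
        b = optimize_all(sphere_problem(), default_configs(20, 40, seed=5))
        for k in a:
            assert np.array_equal(a[k].best_x, b[k].best_x)
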