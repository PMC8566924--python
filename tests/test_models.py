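import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cultivopt.dataset import trait_matrix
from cultivopt.metrics import compute_metrics
from cultivopt.models import (
    ModelError,
    SurrogateModel,
    evaluate_cv,
    fit_anfis,
    fit_grnn,
    fit_mlp,
    select_hidden_size,
    select_sigma,
)
from cultivopt.preprocessing import make_folds
from cultivopt.synthetic_data import SurfaceConfig, make_surface


@pytest.fixture()
def two_point_model():
    """Training set {(0 → 0), (1 → 1)} on a single input."""
    return fit_grnn(np.array([[0.0], [1.0]]), np.array([0.0, 1.0]), sigma=1.0)


class TestGRNN:
    def test_two_point_worked_example(self, two_point_model):
        # kernel weights at x=0: 1 and exp(-1/2) ⇒ ŷ = e^{-1/2}/(1+e^{-1/2})
        pred = two_point_model.predict([[0.0]])[0]
        assert pred == pytest.approx(0.37754, abs=1e-5)

    def test_midpoint_symmetry(self, two_point_model):
        assert two_point_model.predict([[0.5]])[0] == pytest.approx(0.5)

    def test_small_sigma_limit_interpolates(self):
        X = np.array([[0.0], [1.0]])
        m = fit_grnn(X, np.array([0.0, 1.0]), sigma=1e-8)
        assert m.predict(X) == pytest.approx([0.0, 1.0], abs=1e-12)

    def test_large_sigma_limit_predicts_mean(self, rng):
        X = rng.random((20, 3))
        y = rng.random(20)
        m = fit_grnn(X, y, sigma=1e6)
        assert m.predict(rng.random((5, 3))) == pytest.approx(
            np.full(5, y.mean()), rel=1e-6
        )

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=25)
    def test_convex_combination_bound(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((15, 4))
        y = rng.normal(size=15)
        sigma = float(10 ** rng.uniform(-2, 1))
        m = fit_grnn(X, y, sigma)
        preds = m.predict(rng.uniform(-0.5, 1.5, size=(30, 4)))
        assert (preds >= y.min() - 1e-9).all()
        assert (preds <= y.max() + 1e-9).all()

    def test_fixture_prediction_bounded_by_best_treatment(self, table1, rng):
        X, y = trait_matrix(table1, "shoot_length")
        m = fit_grnn(X, y, sigma=0.2, use_boxcox=True)
        queries = rng.random((300, 5)) * [100, 100, 100, 100, 5] + [0, 0, 0, 0, 1]
        assert m.predict(queries).max() <= 154.68 + 1e-9

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ModelError, match="sigma"):
            fit_grnn(np.zeros((3, 1)), np.arange(3.0), sigma=0.0)


class TestSigmaSelection:
    def test_noiseless_smooth_target_prefers_small_sigma(self):
        rng = np.random.default_rng(0)
        X = np.sort(rng.random((120, 1)), axis=0)
        y = 3.0 * X[:, 0]
        plan = make_folds(120, 5, 1, 0)
        grid = (0.02, 0.1, 0.5, 2.0)
        assert select_sigma(X, y, plan, grid, use_boxcox=False) <= 0.1

    def test_pure_noise_prefers_large_sigma(self):
        rng = np.random.default_rng(1)
        X = rng.random((200, 1))
        y = rng.normal(size=200)
        plan = make_folds(200, 5, 5, 0)
        grid = (0.02, 0.1, 0.5, 2.0)
        assert select_sigma(X, y, plan, grid, use_boxcox=False) >= 0.5

    def test_single_candidate_grid(self, table1):
        X, y = trait_matrix(table1, "shoot_length")
        plan = make_folds(66, 5, 1, 0)
        assert select_sigma(X, y, plan, grid=(0.3,)) == 0.3

    def test_empty_grid_rejected(self, table1):
        X, y = trait_matrix(table1, "shoot_length")
        with pytest.raises(ModelError):
            select_sigma(X, y, make_folds(66, 5, 1, 0), grid=())


class TestMLP:
    def test_linear_target_fit_to_high_r2(self, rng):
        X = rng.random((50, 3))
        y = 3.0 * X[:, 0]
        m = fit_mlp(X, y, hidden_size=2, seed=1)
        assert compute_metrics(y, m.predict(X)).r2 > 0.999

    def test_same_seed_identical_weights(self, rng):
        X = rng.random((30, 2))
        y = X[:, 0] - X[:, 1] ** 2
        a = fit_mlp(X, y, hidden_size=3, seed=5)
        b = fit_mlp(X, y, hidden_size=3, seed=5)
        assert np.array_equal(a.core.W1, b.core.W1)
        assert np.array_equal(a.core.w2, b.core.w2)

    def test_forward_pass_matches_direct_formula(self, rng):
        X = rng.random((20, 4))
        y = rng.normal(size=20)
        m = fit_mlp(X, y, hidden_size=3, seed=0)
        c = m.core
        Xq = rng.random((7, 4))
        Xs = m.scaler.transform(Xq)
        # ŷ = Σ_j w_j · tanh(Σ_i w_ji x_i + w_j0) + w_0, then unstandardize
        by_hand = np.array(
            [
                sum(
                    c.w2[j] * np.tanh(c.W1[j] @ x + c.b1[j])
                    for j in range(3)
                )
                + c.b2
                for x in Xs
            ]
        ) * c.y_std + c.y_mean
        assert m.predict(Xq) == pytest.approx(by_hand, rel=1e-12)

    def test_zero_hidden_size_rejected(self, rng):
        with pytest.raises(ModelError):
            fit_mlp(rng.random((10, 2)), rng.random(10), hidden_size=0)

    def test_single_candidate_hidden_size(self, rng):
        X = rng.random((30, 2))
        y = X[:, 0]
        plan = make_folds(30, 3, 1, 0)
        assert select_hidden_size(X, y, plan, candidates=(4,)) == 4

    def test_candidates_outside_range_rejected(self, rng):
        X = rng.random((30, 2))
        with pytest.raises(ModelError):
            select_hidden_size(X, X[:, 0], make_folds(30, 3, 1, 0), (0, 4))


class TestANFIS:
    def test_membership_is_one_at_its_center(self, rng):
        X = rng.random((40, 2))
        m = fit_anfis(X, X[:, 0] + 1.0, mf_per_input=3, epochs=0)
        core = m.core
        for i in range(2):
            for j in range(3):
                q = np.array([[0.5, 0.5]])
                q[0, i] = core.centers[i, j]
                assert core.memberships(q)[0, i, j] == pytest.approx(1.0)

    def test_normalized_firing_strengths_sum_to_one(self, rng):
        X = rng.random((40, 3))
        m = fit_anfis(X, X.sum(axis=1), mf_per_input=3, epochs=2)
        wbar = m.core.normalized_firing(rng.random((25, 3)))
        assert wbar.sum(axis=1) == pytest.approx(np.ones(25))

    def test_linear_target_recovered_noiselessly(self, rng):
        X = rng.random((60, 2))
        y = 2.0 * X[:, 0] + 3.0
        m = fit_anfis(X, y, mf_per_input=3, epochs=10)
        assert compute_metrics(y, m.predict(X)).rmse < 1e-3

    def test_constant_consequents_predict_the_constant(self, rng):
        X = rng.random((30, 2))
        m = fit_anfis(X, X[:, 0], mf_per_input=3, epochs=0)
        core = m.core
        theta = np.zeros((core.n_rules, 3))
        theta[:, -1] = 4.25  # κ in every rule consequent
        import dataclasses

        const_core = dataclasses.replace(core, theta=theta.ravel())
        assert const_core.predict(rng.random((10, 2))) == pytest.approx(
            np.full(10, 4.25)
        )

    def test_rule_explosion_capped_with_advice(self, rng):
        X = rng.random((40, 5))
        with pytest.raises(ModelError, match="fewer membership"):
            fit_anfis(X, X[:, 0], mf_per_input=4, epochs=1)

    def test_mf_count_bounds(self, rng):
        X = rng.random((20, 2))
        with pytest.raises(ModelError):
            fit_anfis(X, X[:, 0], mf_per_input=2)

    def test_conventional_membership_flag(self, rng):
        X = rng.random((30, 1))
        m = fit_anfis(X, X[:, 0], mf_per_input=3, epochs=0, conventional_mf=True)
        core = m.core
        c, a = core.centers[0, 1], core.widths[0, 1]
        q = np.array([[c + a]])
        assert core.memberships(q)[0, 0, 1] == pytest.approx(np.exp(-0.5))


class TestSerialization:
    @pytest.mark.parametrize("family", ["grnn", "mlp", "anfis"])
    def test_json_round_trip(self, rng, family, table1):
        X, y = trait_matrix(table1, "node_number")
        fit = {
            "grnn": lambda: fit_grnn(X, y, 0.3, use_boxcox=True),
            "mlp": lambda: fit_mlp(X, y, 2, seed=0, use_boxcox=True),
            "anfis": lambda: fit_anfis(X, y, 3, epochs=2, use_boxcox=True),
        }[family]
        m = fit()
        back = SurrogateModel.from_json(m.to_json())
        q = rng.random((10, 5)) * [100, 100, 100, 100, 5] + [0, 0, 0, 0, 1]
        assert back.predict(q) == pytest.approx(m.predict(q), rel=1e-12)


class TestCrossValidation:
    def test_report_has_one_row_per_pair_and_partition(self, table1):
        X, y = trait_matrix(table1, "shoot_length")
        plan = make_folds(66, 5, 2, 0)
        rep = evaluate_cv("grnn", X, y, plan, {"sigma": 0.3})
        counts = rep.frame["partition"].value_counts()
        assert counts["train"] == 10 and counts["test"] == 10

    def test_grnn_learns_noiseless_smooth_surface(self):
        # 2-D smooth surface, space-filling design: kernel regression
        # should explain essentially all the variance
        surf = make_surface(
            1, SurfaceConfig(noise_cv=0.0, bounds=((0.0, 100.0), (1.0, 6.0)))
        )
        rng = np.random.default_rng(1)
        lb, ub = surf.bounds[:, 0], surf.bounds[:, 1]
        X = lb + (ub - lb) * rng.random((150, 2))
        y = surf(X)
        plan = make_folds(150, 5, 2, 3)
        sigma = select_sigma(X, y, plan)
        rep = evaluate_cv("grnn", X, y, plan, {"sigma": sigma})
        assert rep.mean("r2", "test") > 0.95

    def test_train_fit_exceeds_test_fit_on_noisy_data(self):
        surf = make_surface(2, SurfaceConfig(noise_cv=0.0, bounds=((0.0, 100.0), (1.0, 6.0))))
        rng = np.random.default_rng(2)
        lb, ub = surf.bounds[:, 0], surf.bounds[:, 1]
        X = lb + (ub - lb) * rng.random((100, 2))
        y = surf(X) * rng.lognormal(sigma=0.2, size=100)
        plan = make_folds(100, 5, 2, 3)
        rep = evaluate_cv("grnn", X, y, plan, {"sigma": 0.1})
        assert rep.mean("r2", "train") >= rep.mean("r2", "test") - 0.02

    def test_transforms_fit_on_train_only_no_leakage(self, table1):
        # a fold whose test targets exceed the train range cannot leak:
        # GRNN predictions stay within the train-target range
        X, y = trait_matrix(table1, "shoot_length")
        plan = make_folds(66, 5, 1, 4)
        from cultivopt.models import fit_family

        train, test = plan.pairs[0]
        m = fit_family("grnn", X[train], y[train], {"sigma": 0.2, "use_boxcox": True})
        assert m.predict(X[test]).max() <= y[train].max() + 1e-9
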