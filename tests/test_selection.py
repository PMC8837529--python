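import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from dekernet import (
    GridConfig,
    Hyperparameters,
    KernelConfig,
    MarginProblem,
    SolverConfig,
    ZERO_TOLERANCE,
    lambda_max,
    model_bic,
    null_bic,
    optimize_weights,
    platt_calibrate,
    platt_log_likelihood,
    select_features,
    valid_thresholds,
)
from dekernet.fixtures import planted_regression, pure_noise_regression, separating_feature
from dekernet.selection import standardize_columns


class TestOptimizeWeights:
    def test_huge_penalty_drives_all_weights_to_zero(self, rng):
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        problem = MarginProblem(standardize_columns(X), y, KernelConfig(1.0))
        lam = 50.0 * max(lambda_max(problem), 1.0)
        res = optimize_weights(
            standardize_columns(X), y, Hyperparameters(1.0, lam), problem=problem
        )
        assert np.all(res.w <= ZERO_TOLERANCE)
        assert res.selected.size == 0

    def test_planted_predictor_recovered(self):
        X, y = planted_regression(seed=0)
        Xs = standardize_columns(X)
        problem = MarginProblem(Xs, y, KernelConfig(1.0))
        lam = 0.05 * lambda_max(problem)
        res = optimize_weights(Xs, y, Hyperparameters(1.0, lam), problem=problem)
        assert 0 in res.selected
        assert res.w[0] > ZERO_TOLERANCE
        # the planted feature dominates every noise feature
        assert np.all(res.w[0] >= res.w[1:])

    @pytest.mark.parametrize("method", ["lbfgsb", "projected_gradient"])
    def test_two_runs_are_bitwise_identical(self, rng, method):
        X = standardize_columns(rng.normal(size=(15, 3)))
        y = rng.normal(size=15)
        hp = Hyperparameters(1.0, 0.5)
        cfg = SolverConfig(method=method, max_iter=100)
        r1 = optimize_weights(X, y, hp, solver_config=cfg)
        r2 = optimize_weights(X, y, hp, solver_config=cfg)
        assert np.array_equal(r1.w, r2.w)

    def test_solvers_agree_on_easy_instance(self):
        X, y = planted_regression(seed=3, n_samples=30, n_noise_features=2)
        Xs = standardize_columns(X)
        hp = Hyperparameters(1.0, 1.0)
        w_a = optimize_weights(Xs, y, hp, solver_config=SolverConfig("lbfgsb")).w
        w_b = optimize_weights(
            Xs, y, hp, solver_config=SolverConfig("projected_gradient", max_iter=2000)
        ).w
        assert np.allclose(w_a, w_b, atol=5e-3)

    def test_nonconvergence_is_flagged_not_raised(self, rng):
        X = standardize_columns(rng.normal(size=(15, 3)))
        y = rng.normal(size=15)
        res = optimize_weights(
            X, y, Hyperparameters(1.0, 0.01), solver_config=SolverConfig(max_iter=1, tol=0.0)
        )
        assert not res.converged


class TestPlattCalibration:
    def test_constant_scores_give_smoothed_base_rate(self):
        scores = np.zeros(10)
        labels = np.array([1] * 7 + [0] * 3)
        cal = platt_calibrate(scores, labels)
        # smoothed targets: positives (7+1)/(7+2), negatives 1/(3+2); the
        # constant fit lands at their mean
        want = np.mean([8 / 9] * 7 + [1 / 5] * 3)
        assert cal.slope == 0.0
        assert cal.probability(np.zeros(1))[0] == pytest.approx(want, abs=1e-6)

    def test_perfect_separation_stays_bounded(self):
        scores = np.concatenate([np.linspace(0.5, 2, 20), np.linspace(-2, -0.5, 20)])
        labels = np.array([1] * 20 + [0] * 20)
        cal = platt_calibrate(scores, labels)
        p = cal.probability(scores)
        assert np.all(p < 1.0) and np.all(p > 0.0)
        assert cal.slope < 0  # larger score => higher probability

    def test_matches_independent_logistic_fit_with_smoothed_targets(self):
        rng = np.random.default_rng(7)
        scores = np.tile([0.5, -0.5, 1.0, -1.0], 10)
        labels = (scores + 0.3 * rng.normal(size=40)) > 0
        n_pos = labels.sum()
        n_neg = 40 - n_pos
        t = np.where(labels, (n_pos + 1) / (n_pos + 2), 1 / (n_neg + 2))

        def nll(params):
            p = np.clip(expit(-(params[0] * scores + params[1])), 1e-12, 1 - 1e-12)
            return -np.sum(t * np.log(p) + (1 - t) * np.log(1 - p))

        ref = minimize(nll, np.array([-1.0, 0.0]), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        cal = platt_calibrate(scores, labels)
        assert cal.slope == pytest.approx(ref.x[0], abs=1e-4)
        assert cal.intercept == pytest.approx(ref.x[1], abs=1e-4)

    def test_slope_never_positive(self):
        # anti-correlated scores: the bound clamps the slope at zero
        scores = np.array([-1.0, -2.0, 1.0, 2.0])
        labels = np.array([1, 1, 0, 0])
        cal = platt_calibrate(scores, labels)
        assert cal.slope <= 0.0


class TestBic:
    def test_extra_feature_costs_log_n_obs(self, rng):
        X = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        mt = MarginProblem(X, y, KernelConfig(1.0)).margins(np.ones(2))
        cal = platt_calibrate(mt.decision.ravel(), mt.labels.ravel())
        b1 = model_bic(mt, cal, n_selected=1)
        b2 = model_bic(mt, cal, n_selected=2)
        assert b2 - b1 == pytest.approx(np.log(mt.m.shape[0]), rel=1e-12)

    def test_separating_fixture_bic_composes_margin_and_platt_oracles(self):
        from oracles import naive_margins

        X, y = separating_feature()
        ts = valid_thresholds(y)
        m_oracle = naive_margins(X, y, np.ones(1), 1.0, ts)
        labels = np.where(y[:, None] < ts[None, :], -1.0, 1.0)
        decision = m_oracle * labels
        cal = platt_calibrate(decision.ravel(), labels.ravel())
        ll = platt_log_likelihood(decision, labels, cal)
        want = -2.0 * ll / len(ts) + 3 * np.log(len(y))
        mt = MarginProblem(X, y, KernelConfig(1.0)).margins(np.ones(1))
        got = model_bic(mt, cal, n_selected=1)
        assert got == pytest.approx(want, abs=1e-8)

    def test_null_bic_balanced_closed_form(self):
        # y = (0, 0, 1, 1): one valid threshold (t=1) with a 2/2 split
        y = np.array([0.0, 0.0, 1.0, 1.0])
        p = (2 + 1) / (4 + 2)
        assert null_bic(y) == pytest.approx(-2 * 4 * np.log(p))

    def test_null_bic_counts_valid_thresholds(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        # 3 valid thresholds (the minimum is skipped); hand-computed deviance
        ll = 0.0
        for n_below in (1, 2, 3):
            n_above = 4 - n_below
            ll += n_below * np.log((n_below + 1) / 6) + n_above * np.log((n_above + 1) / 6)
        assert null_bic(y) == pytest.approx(-2 * ll / 3)


class TestSelectFeatures:
    def test_pure_noise_is_uninformative(self):
        X, y = pure_noise_regression(seed=0)
        res = select_features(X, y)
        assert not res.informative
        assert res.selected == ()

    def test_planted_predictor_selected_exactly(self):
        X, y = planted_regression(seed=0)
        res = select_features(X, y)
        assert res.informative
        assert res.selected == (0,)
        assert res.best_model.bic < res.null_bic

    def test_single_point_grid_reduces_to_one_fit(self):
        X, y = planted_regression(seed=0, n_samples=40, n_noise_features=3)
        res = select_features(X, y, lengthscale_grid_values=[1.0], penalty_grid_values=[2.0])
        assert len(res.grid_trace) == 1
        hp = res.grid_trace[0][0]
        assert (hp.lengthscale, hp.penalty) == (1.0, 2.0)

    def test_selected_count_non_increasing_in_penalty(self):
        X, y = planted_regression(seed=0, n_samples=40, n_noise_features=3)
        res = select_features(
            X, y, lengthscale_grid_values=[1.0],
            penalty_grid_values=np.geomspace(0.1, 200, 6),
        )
        counts = [n for hp, _, n in sorted(res.grid_trace, key=lambda t: t[0].penalty)]
        assert counts == sorted(counts, reverse=True)

    def test_informative_result_never_has_empty_selection(self):
        for seed in range(4):
            X, y = pure_noise_regression(seed=seed, n_samples=30, n_features=3)
            res = select_features(
                X, y,
                grid=GridConfig(n_lengthscales=3, n_penalties=3),
            )
            if res.informative:
                assert len(res.selected) > 0

    def test_duplicating_margin_observations_keeps_bic_gate_direction(self):
        # replicating every margin observation (threshold columns doubled)
        # must not flip the sign of model BIC minus null BIC
        from dekernet import MarginTable

        for make, seed in [(planted_regression, 0), (pure_noise_regression, 0)]:
            X, y = make(seed=seed)
            res = select_features(X, y, grid=GridConfig(n_lengthscales=3, n_penalties=3))
            bm = res.best_model
            problem = MarginProblem(
                standardize_columns(X), y, KernelConfig(bm.hyperparameters.lengthscale)
            )
            mt = problem.margins(bm.weights)
            ts = valid_thresholds(y)
            base = model_bic(mt, bm.calibration, len(bm.selected)) - null_bic(y, ts)
            mt2 = MarginTable(
                m=np.tile(mt.m, (1, 2)),
                labels=np.tile(mt.labels, (1, 2)),
                thresholds=np.tile(mt.thresholds, 2),
            )
            dup = model_bic(mt2, bm.calibration, len(bm.selected)) - null_bic(
                y, np.tile(ts, 2)
            )
            assert np.sign(base) == np.sign(dup)

    def test_deterministic_given_inputs(self):
        X, y = planted_regression(seed=2, n_samples=30, n_noise_features=3)
        r1 = select_features(X, y, grid=GridConfig(n_lengthscales=3, n_penalties=3))
        r2 = select_features(X, y, grid=GridConfig(n_lengthscales=3, n_penalties=3))
        assert r1.selected == r2.selected
        assert r1.best_model.bic == r2.best_model.bic
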