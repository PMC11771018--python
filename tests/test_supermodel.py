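"""Penalized stacked Cox solver: likelihood, fitting, baseline, prediction."""

import json

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from landmarker import (
    Cohort,
    LandmarkGrid,
    LandmarkSupermodel,
    TDSpec,
    build_stack,
    cv_lambda,
    expand_design,
    fit_csc,
    fit_pencox,
    neg_log_ipl,
)
from landmarker._coxsolver import CoxData, breslow_increments, fit_penalized, lambda_max
from conftest import random_cohort


def brute_force_nll(beta, X, entry, exit_, status, cause=1):
    """Direct double loop over event rows and pooled risk sets."""
    lp = X @ beta
    total = 0.0
    for i in range(len(exit_)):
        if status[i] != cause:
            continue
        t = exit_[i]
        denom = sum(
            np.exp(lp[j]) for j in range(len(exit_)) if entry[j] < t <= exit_[j]
        )
        total += lp[i] - np.log(denom)
    return -total


def single_landmark_frame(rng, n=120, p=3):
    X = rng.standard_normal((n, p))
    beta = np.array([0.8, -0.5, 0.0])
    T = rng.exponential(np.exp(-X @ beta))
    C = rng.exponential(2.0, n)
    time = np.minimum(T, C)
    ev = (T <= C).astype(int)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
    df["time"], df["ev"] = time, ev
    return df


class TestNegLogIPL:
    def test_uniform_risk_set_of_two(self):
        X = np.zeros((2, 1))
        val = neg_log_ipl(np.zeros(1), X, [0.0, 0.0], [1.0, 2.0], [1, 0])
        assert val == pytest.approx(np.log(2.0), abs=1e-12)

    def test_zero_coefs_sum_of_log_risk_sizes(self, rng):
        n = 25
        entry = np.zeros(n)
        exit_ = np.sort(rng.exponential(1.0, n)) + 0.01
        status = rng.integers(0, 2, n)
        val = neg_log_ipl(np.zeros(2), np.zeros((n, 2)), entry, exit_, status)
        sizes = [np.sum((entry < t) & (t <= exit_)) for t in exit_[status == 1]]
        assert val == pytest.approx(sum(np.log(s) for s in sizes), abs=1e-10)

    def test_matches_brute_force_double_loop(self, rng):
        n = 30
        X = rng.standard_normal((n, 2))
        entry = rng.uniform(0, 1, n)
        exit_ = entry + rng.exponential(1.0, n) + 1e-3
        status = rng.integers(0, 2, n)
        status[:3] = 1  # ensure events
        beta = np.array([0.4, -0.7])
        got = neg_log_ipl(beta, X, entry, exit_, status)
        want = brute_force_nll(beta, X, entry, exit_, status)
        assert got == pytest.approx(want, abs=1e-10)


class TestUnpenalizedOracle:
    """With a single landmark, basis {1} and lam=0 the supermodel IS plain Cox."""

    def test_coefficients_match_reference(self, rng):
        df = single_landmark_frame(rng)
        p = 3
        X = df[[f"x{i}" for i in range(p)]].to_numpy()
        res = fit_penalized(
            X, np.zeros(len(df)), df["time"].to_numpy(), df["ev"].to_numpy(),
            lam=0.0, tol=1e-10,
        )
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="ev")
        np.testing.assert_allclose(res.beta, cph.params_.to_numpy(), atol=1e-4)

    def test_breslow_baseline_matches_reference(self, rng):
        df = single_landmark_frame(rng)
        X = df[[f"x{i}" for i in range(3)]].to_numpy()
        data = CoxData(np.zeros(len(df)), df["time"].to_numpy(),
                       df["ev"].to_numpy() == 1)
        cph = CoxPHFitter(baseline_estimation_method="breslow")
        cph.fit(df, duration_col="time", event_col="ev")
        # evaluate both Breslow formulas at the reference coefficients
        times, incr = breslow_increments(data, X @ cph.params_.to_numpy())
        ref = cph.baseline_cumulative_hazard_["baseline cumulative hazard"]
        ours = np.cumsum(incr)
        # lifelines anchors its baseline at the covariate means
        anchor = float(np.exp(-X.mean(axis=0) @ cph.params_.to_numpy()))
        theirs = np.interp(times, ref.index.to_numpy(), ref.to_numpy()) * anchor
        np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_zero_coefs_nelson_aalen(self):
        n = 8
        exit_ = np.arange(1.0, n + 1)
        data = CoxData(np.zeros(n), exit_, np.ones(n, dtype=bool))
        _, incr = breslow_increments(data, np.zeros(n))
        np.testing.assert_allclose(incr, 1.0 / np.arange(n, 0, -1.0), atol=1e-12)

    def test_baseline_nondecreasing_from_zero(self, rng):
        coh = random_cohort(rng, n=60)
        model = fit_pencox(build_stack(coh, LandmarkGrid((0.0, 0.5), 2.0)))
        b = model.baselines_[1]
        assert np.all(b.increments >= 0)
        assert b.cum(0.0) == 0.0


class TestPenalization:
    def _stack_design(self, rng, n=80):
        coh = random_cohort(rng, n=n)
        stack = build_stack(coh, LandmarkGrid((0.0, 0.5), 2.0))
        design, _ = expand_design(stack, TDSpec.from_names("linear", "quadratic"))
        return (design.to_numpy(), stack.data["entry"].to_numpy(),
                stack.data["exit"].to_numpy(), stack.data["status"].to_numpy())

    def test_ridge_norm_monotone_along_path(self, rng):
        X, entry, exit_, status = self._stack_design(rng)
        lams = [0.1, 1.0, 5.0, 25.0]
        norms = [
            np.linalg.norm(fit_penalized(X, entry, exit_, status, lam=l).beta_std)
            for l in lams
        ]
        assert all(b <= a + 1e-9 for a, b in zip(norms, norms[1:]))

    def test_lasso_all_zero_above_lambda_max(self, rng):
        X, entry, exit_, status = self._stack_design(rng)
        Xs = (X - X.mean(0)) / X.std(0)
        data = CoxData(entry, exit_, status == 1)
        lmax = lambda_max(data, Xs, 1.0, np.ones(X.shape[1]))
        res = fit_penalized(X, entry, exit_, status, lam=lmax * 1.01, l1_ratio=1.0)
        np.testing.assert_array_equal(res.beta, 0.0)
        res2 = fit_penalized(X, entry, exit_, status, lam=lmax * 0.5, l1_ratio=1.0)
        assert np.any(res2.beta != 0.0)

    def test_objective_monotone_decreasing(self, rng):
        X, entry, exit_, status = self._stack_design(rng)
        for lam, l1 in [(0.0, 0.0), (2.0, 1.0), (1.0, 0.5)]:
            path = fit_penalized(X, entry, exit_, status, lam=lam, l1_ratio=l1).objective_path
            assert all(b <= a + 1e-9 for a, b in zip(path, path[1:]))

    def test_optimum_not_worse_than_zero_vector(self, rng):
        X, entry, exit_, status = self._stack_design(rng)
        res = fit_penalized(X, entry, exit_, status, lam=1.5, l1_ratio=0.5)
        obj_zero = neg_log_ipl(np.zeros(X.shape[1]), X, entry, exit_, status)
        assert res.objective_path[-1] <= obj_zero + 1e-9

    def test_rescaling_invariance_unpenalized(self, rng):
        X, entry, exit_, status = self._stack_design(rng)
        res = fit_penalized(X, entry, exit_, status, lam=0.0, tol=1e-9)
        scales = 1.0 + np.arange(X.shape[1]) * 0.5
        res2 = fit_penalized(X * scales, entry, exit_, status, lam=0.0, tol=1e-9)
        np.testing.assert_allclose(X @ res.beta, (X * scales) @ res2.beta, atol=1e-5)


class TestCauseSpecific:
    def _two_cause_cohort(self, rng, n=150, symmetric=False):
        X = rng.standard_normal((n, 2))
        b1 = np.array([0.6, -0.4])
        b2 = b1 if symmetric else np.array([-0.2, 0.5])
        T1 = rng.exponential(np.exp(-X @ b1))
        T2 = rng.exponential(np.exp(-X @ b2))
        T = np.minimum(np.minimum(T1, T2), 4.0)
        status = np.where(T1 <= T2, 1, 2)
        status[(T1 > 4.0) & (T2 > 4.0)] = 0
        out = pd.DataFrame({"id": np.arange(n), "time": T, "status": status})
        meas = pd.DataFrame({"id": np.arange(n), "obs_time": 0.0,
                             "x1": X[:, 0], "x2": X[:, 1]})
        return Cohort(out, meas, n_causes=2)

    def test_cause1_equals_single_cause_fit(self, rng):
        coh = self._two_cause_cohort(rng)
        stack = build_stack(coh, LandmarkGrid((0.0, 0.5), 2.0))
        both = fit_csc(stack)
        single = fit_pencox(stack)  # relabels cause 2 as censored
        np.testing.assert_allclose(
            both.coef_["cause_1"].to_numpy(), single.coef_["cause_1"].to_numpy(),
            atol=1e-10,
        )

    def test_symmetric_causes_give_equal_coefficients(self, rng):
        coh = self._two_cause_cohort(rng, n=4000, symmetric=True)
        stack = build_stack(coh, LandmarkGrid((0.0,), 2.0))
        model = fit_csc(stack, spec=TDSpec.from_names("const", "none"))
        c1 = model.coef_["cause_1"].to_numpy()
        c2 = model.coef_["cause_2"].to_numpy()
        np.testing.assert_allclose(c1, c2, atol=0.15)

    def test_single_cause_input_rejected(self, rng):
        coh = random_cohort(rng, n=40)
        stack = build_stack(coh, LandmarkGrid((0.0,), 2.0))
        with pytest.raises(ValueError, match="J >= 2"):
            fit_csc(stack)

    def test_cause_without_events_rejected(self, rng):
        coh = self._two_cause_cohort(rng, n=60)
        coh.outcomes.loc[coh.outcomes["status"] == 2, "status"] = 1
        stack = build_stack(coh, LandmarkGrid((0.0,), 2.0))
        stack.n_causes = 2
        with pytest.raises(ValueError, match="cause 2"):
            fit_csc(stack)

    def test_competing_risk_conservation(self, rng):
        coh = self._two_cause_cohort(rng, n=200)
        model = LandmarkSupermodel(landmarks=(0.0, 0.5, 1.0), window=2.0).fit(coh)
        cov = coh.measurements[["x1", "x2"]]
        for s in (0.0, 0.5, 1.0):
            F = model.predict_risk(cov, s)
            S = model.predict_survival(cov, s)
            np.testing.assert_allclose(F.sum(axis=1) + S, 1.0, atol=1e-10)
            assert np.all((F >= 0) & (F <= 1))
            assert np.all(F.sum(axis=1) <= 1 + 1e-12)


class TestPrediction:
    def _toy_model(self, increments, times, coef=0.0):
        model_dict = {
            "landmarks": [0.0], "window": 5.0, "beta_basis": "const",
            "alpha_basis": "none", "lam": 0.0, "l1_ratio": 0.0, "n_causes": 1,
            "covariate_names": ["x"], "design_columns": ["x"],
            "column_map": [{"column": "x", "covariate": "x", "basis": "1", "kind": "beta"}],
            "coef": {"cause_1": [coef]},
            "baselines": {"1": {"times": times, "increments": increments}},
        }
        return LandmarkSupermodel.from_json(json.dumps(model_dict))

    def test_exponential_closed_form(self):
        # total baseline mass 0.1 inside the window, zero coefficient:
        # predicted risk is exactly 1 - exp(-0.1)
        model = self._toy_model([0.02] * 5, [1.0, 2.0, 3.0, 4.0, 4.5])
        risk = model.predict_risk(pd.DataFrame({"x": [0.0, 2.0]}), 0.0)
        np.testing.assert_allclose(risk[:, 0], 1.0 - np.exp(-0.1), atol=1e-12)

    def test_zero_coefficients_identical_risks(self, rng):
        coh = random_cohort(rng, n=50)
        model = fit_pencox(build_stack(coh, LandmarkGrid((0.0,), 2.0)))
        model.coef_.iloc[:, 0] = 0.0
        risks = model.predict_risk(coh.measurements[["x1", "x2"]], 0.0)[:, 0]
        assert np.ptp(risks) == 0.0

    def test_landmark_outside_grid_rejected(self, rng):
        coh = random_cohort(rng, n=50)
        model = fit_pencox(build_stack(coh, LandmarkGrid((0.0, 1.0), 2.0)))
        with pytest.raises(ValueError, match="outside"):
            model.predict_risk(coh.measurements[["x1", "x2"]], 3.0)

    def test_serialization_round_trip(self, rng):
        coh = random_cohort(rng, n=60)
        model = LandmarkSupermodel(landmarks=(0.0, 0.5), window=2.0, lam=0.5).fit(coh)
        clone = LandmarkSupermodel.from_json(model.to_json())
        cov = coh.measurements[["x1", "x2"]].head(10)
        np.testing.assert_allclose(
            model.predict_risk(cov, 0.5), clone.predict_risk(cov, 0.5), atol=1e-12
        )

    def test_sklearn_param_interface(self):
        model = LandmarkSupermodel(lam=2.0)
        assert model.get_params()["lam"] == 2.0
        model.set_params(lam=0.1, l1_ratio=1.0)
        assert model.lam == 0.1 and model.l1_ratio == 1.0


class TestCVLambda:
    def test_single_lambda_grid_returned(self, rng):
        coh = random_cohort(rng, n=60)
        stack = build_stack(coh, LandmarkGrid((0.0, 0.5), 2.0))
        lam, _ = cv_lambda(stack, lambdas=[0.7], n_folds=3, seed=1)
        assert lam == 0.7

    def test_deterministic_under_seed(self, rng):
        coh = random_cohort(rng, n=80)
        stack = build_stack(coh, LandmarkGrid((0.0, 0.5), 2.0))
        grid = [0.01, 0.1, 1.0, 5.0]
        a, ta = cv_lambda(stack, lambdas=grid, n_folds=4, seed=3, l1_ratio=1.0)
        b, tb = cv_lambda(stack, lambdas=grid, n_folds=4, seed=3, l1_ratio=1.0)
        assert a == b
        pd.testing.assert_frame_equal(ta, tb)

    def test_pure_noise_prefers_heavy_penalty(self):
        hits = 0
        n_sim = 10
        for r in range(n_sim):
            rng = np.random.default_rng(100 + r)
            n = 120
            X = rng.standard_normal((n, 3))
            T = rng.exponential(1.0, n)  # independent of X
            out = pd.DataFrame({"id": np.arange(n), "time": T,
                                "status": np.ones(n, dtype=int)})
            meas = pd.DataFrame({"id": np.arange(n), "obs_time": 0.0,
                                 "x1": X[:, 0], "x2": X[:, 1], "x3": X[:, 2]})
            stack = build_stack(Cohort(out, meas), LandmarkGrid((0.0,), 3.0))
            grid = np.geomspace(3.0, 0.003, 8)
            lam, _ = cv_lambda(stack, lambdas=grid, n_folds=3, seed=r, l1_ratio=1.0)
            if lam >= np.sort(grid)[-3]:  # among the largest grid values
                hits += 1
        assert hits >= 0.8 * n_sim
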