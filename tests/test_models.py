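"""Regressor contracts: SVR against a QP oracle, BPNN descent, PSO tuning."""

import numpy as np
import pytest
from scipy.optimize import minimize

from strengthsense import (
    BpnnConfig,
    FeatureTable,
    PsoConfig,
    SvrConfig,
    load_model,
    predict,
    save_model,
    train_bpnn,
    train_pso_bpnn,
    train_pso_svr,
    train_svr,
)
from strengthsense.models import _cv_rmse_svr, _fit_svr_params
from strengthsense.dataset import SplitSpec, kfold


def _table(X, y, ncols=None):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    cols = tuple(f"f{i}" for i in range(X.shape[1]))
    return FeatureTable(
        X=X, y=np.asarray(y, dtype=float),
        subject_ids=np.array(["s"] * len(y)), column_names=cols,
    )


def _qp_svr_oracle(X, y, C, gamma, epsilon):
    """Independent epsilon-SVR dual solution via SLSQP on the 2n-variable QP.

    minimize  1/2 (a - a*)^T K (a - a*) + eps * sum(a + a*) - y^T (a - a*)
    s.t.      sum(a - a*) = 0,  0 <= a, a* <= C
    """
    n = len(y)
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2)
    K = np.exp(-gamma * d2)

    def obj(z):
        beta = z[:n] - z[n:]
        return 0.5 * beta @ K @ beta + epsilon * np.sum(z) - y @ beta

    def jac(z):
        beta = z[:n] - z[n:]
        g = K @ beta
        return np.concatenate([g + epsilon - y, -g + epsilon + y])

    cons = [{"type": "eq", "fun": lambda z: np.sum(z[:n]) - np.sum(z[n:])}]
    res = minimize(
        obj, x0=np.zeros(2 * n), jac=jac, bounds=[(0.0, C)] * (2 * n),
        constraints=cons, method="SLSQP", options={"maxiter": 500, "ftol": 1e-14},
    )
    beta = res.x[:n] - res.x[n:]
    # intercept from free support vectors (0 < alpha < C strictly)
    tol = 1e-6 * C
    b_vals = []
    for i in range(n):
        if tol < res.x[i] < C - tol:
            b_vals.append(y[i] - epsilon - K[i] @ beta)
        elif tol < res.x[n + i] < C - tol:
            b_vals.append(y[i] + epsilon - K[i] @ beta)
    b = float(np.mean(b_vals)) if b_vals else float(np.mean(y - K @ beta))
    return beta, b, K


class TestSvr:
    def test_small_instance_matches_qp_oracle(self):
        X = np.array([[0.0], [0.3], [0.5], [0.8], [1.0]])
        y = np.array([2.0, 2.7, 3.4, 4.1, 4.6])
        cfg = SvrConfig(C=10.0, gamma=0.5, epsilon=0.1, tol=1e-8)
        model = train_svr(_table(X, y), cfg)
        beta, b, K = _qp_svr_oracle(X, y, cfg.C, cfg.gamma, cfg.epsilon)
        grid = np.linspace(-0.2, 1.2, 30)[:, None]
        d2 = np.sum((grid[:, None, :] - X[None, :, :]) ** 2, axis=2)
        oracle_pred = np.exp(-cfg.gamma * d2) @ beta + b
        np.testing.assert_allclose(predict(model, grid), oracle_pred, atol=1e-4)

    def test_constant_targets_give_flat_zero_slack_solution(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (8, 3))
        y = np.full(8, 3.0)
        model = train_svr(_table(X, y))
        np.testing.assert_allclose(predict(model, X), 3.0, atol=1e-9)

    def test_epsilon_wider_than_range_keeps_all_in_tube(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (10, 2))
        y = 3.0 + 0.2 * rng.uniform(-1, 1, 10)
        model = train_svr(_table(X, y), SvrConfig(epsilon=1.0))
        assert np.all(np.abs(predict(model, X) - y) <= 1.0 + 1e-8)


class TestBpnn:
    def test_fits_linear_response(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (50, 1))
        y = 2.0 + 3.0 * X[:, 0]
        cfg = BpnnConfig(learning_rate=0.1, max_iter=5000, seed=0)
        model = train_bpnn(_table(X, y), cfg)
        pred = predict(model, X)
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot >= 0.99

    def test_constant_targets_predicted(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, (30, 4))
        y = np.full(30, 4.2)
        model = train_bpnn(_table(X, y), BpnnConfig(seed=1, max_iter=3000))
        np.testing.assert_allclose(predict(model, X), 4.2, atol=0.05)

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        X, y = rng.uniform(0, 1, (20, 3)), rng.uniform(2, 5, 20)
        m1 = train_bpnn(_table(X, y), BpnnConfig(seed=7, max_iter=50))
        m2 = train_bpnn(_table(X, y), BpnnConfig(seed=7, max_iter=50))
        np.testing.assert_array_equal(m1.params["weights"], m2.params["weights"])


def _toy_nonlinear(n=40, seed=5):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, (n, 2))
    y = 3.5 + np.sin(2 * np.pi * X[:, 0]) + 0.5 * X[:, 1] + 0.05 * rng.standard_normal(n)
    return _table(X, y)


class TestPsoSvr:
    def test_tuned_cv_rmse_not_worse_than_default(self):
        table = _toy_nonlinear()
        pso_cfg = PsoConfig(
            bounds=((1.0, 100.0), (0.001, 1.0)), n_particles=6, n_iters=15,
            c1=1.7, c2=1.7, seed=3,
        )
        model = train_pso_svr(table, ((1.0, 100.0), (0.001, 1.0)), pso_cfg)
        folds = kfold(table.n, SplitSpec(seed=pso_cfg.seed, folds=5))
        default_cv = _cv_rmse_svr(table.X, table.y, SvrConfig(), folds)
        assert model.meta["pso_gbest_fitness"] <= default_cv + 1e-12

    def test_degenerate_budget_still_returns_model(self):
        table = _toy_nonlinear(n=25)
        pso_cfg = PsoConfig(
            bounds=((1.0, 100.0), (0.001, 1.0)), n_particles=1, n_iters=1, seed=0
        )
        model = train_pso_svr(table, ((1.0, 100.0), (0.001, 1.0)), pso_cfg)
        assert predict(model, table.X).shape == (25,)

    def test_seed_determinism(self):
        table = _toy_nonlinear(n=30)
        pso_cfg = PsoConfig(
            bounds=((1.0, 100.0), (0.001, 1.0)), n_particles=4, n_iters=5, seed=9
        )
        m1 = train_pso_svr(table, pso_cfg=pso_cfg)
        m2 = train_pso_svr(table, pso_cfg=pso_cfg)
        assert m1.meta["config"] == m2.meta["config"]
        np.testing.assert_array_equal(m1.params["dual_coef"], m2.params["dual_coef"])


class TestPsoBpnn:
    def test_pso_phase_dominates_initial_swarm(self):
        table = _toy_nonlinear(n=30)
        model = train_pso_bpnn(table, BpnnConfig(seed=2, max_iter=100))
        trace = model.meta["pso_trace"]
        assert trace[-1] <= trace[0]

    def test_fine_tune_never_worse_than_swarm_optimum(self):
        table = _toy_nonlinear(n=30)
        model = train_pso_bpnn(table, BpnnConfig(seed=4, max_iter=200))
        assert model.meta["train_mse"] <= model.meta["pso_gbest_fitness"] + 1e-12

    def test_seed_determinism(self):
        table = _toy_nonlinear(n=20)
        m1 = train_pso_bpnn(table, BpnnConfig(seed=6, max_iter=30))
        m2 = train_pso_bpnn(table, BpnnConfig(seed=6, max_iter=30))
        np.testing.assert_array_equal(m1.params["weights"], m2.params["weights"])


class TestPredict:
    def test_batch_equals_single_rows(self):
        table = _toy_nonlinear(n=20)
        model = train_svr(table)
        batch = predict(model, table.X)
        singles = np.array([predict(model, row)[0] for row in table.X])
        np.testing.assert_allclose(batch, singles, rtol=1e-12)

    def test_column_mismatch_rejected(self):
        table = _toy_nonlinear(n=15)
        model = train_svr(table)
        with pytest.raises(ValueError):
            predict(model, np.zeros((3, 5)))

    def test_clip_grades_flag(self):
        table = _toy_nonlinear(n=20)
        model = train_svr(table)
        clipped = predict(model, np.full((1, 2), 100.0), clip_grades=True)
        assert 2.0 <= clipped[0] <= 5.0

    @pytest.mark.parametrize("trainer", [train_svr, train_bpnn])
    def test_save_load_round_trip(self, trainer, tmp_path):
        table = _toy_nonlinear(n=20)
        model = trainer(table)
        path = save_model(model, tmp_path / "m.json")
        back = load_model(path)
        np.testing.assert_array_equal(predict(model, table.X), predict(back, table.X))
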