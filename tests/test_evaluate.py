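"""Metric closed forms and identities; harness and statistical comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from strengthsense import metrics, rm_anova, run_experiment, compare_models
from strengthsense.evaluate import METRIC_ORDER, EvalReport


def test_perfect_prediction():
    m = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (m.r2, m.rmse, m.mae, m.mbe) == (1.0, 0.0, 0.0, 0.0)


def test_hand_computed_triple():
    m = metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
    assert m.r2 == pytest.approx(0.0, abs=1e-12)
    assert m.rmse == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-12)
    assert m.mae == pytest.approx(2.0 / 3.0, abs=1e-12)
    assert m.mbe == pytest.approx(0.0, abs=1e-12)


def test_constant_offset_closed_form():
    actual = np.array([2.0, 3.0, 4.0])
    m = metrics(actual, actual + 0.5)
    # MBE = mean(actual - predicted) = -0.5 under this sign convention
    assert m.mbe == pytest.approx(-0.5)
    assert m.mae == pytest.approx(0.5)
    assert m.rmse == pytest.approx(0.5)
    m_flipped = metrics(actual, actual + 0.5, flip_mbe=True)
    assert m_flipped.mbe == pytest.approx(0.5)


def test_constant_actual_rejected():
    with pytest.raises(ValueError):
        metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        metrics([1.0, 2.0], [1.0])


vecs = st.integers(2, 40).flatmap(
    lambda n: st.tuples(
        st.lists(st.floats(-100, 100), min_size=n, max_size=n),
        st.lists(st.floats(-100, 100), min_size=n, max_size=n),
    )
)


@given(vecs)
@settings(max_examples=150, deadline=None)
def test_error_magnitude_ordering(pair):
    a, p = np.asarray(pair[0]), np.asarray(pair[1])
    if np.sum((a - a.mean()) ** 2) == 0:
        return
    m = metrics(a, p)
    assert m.rmse >= m.mae - 1e-9
    assert m.mae >= abs(m.mbe) - 1e-9


@given(vecs)
@settings(max_examples=100, deadline=None)
def test_r2_rmse_identity(pair):
    a, p = np.asarray(pair[0]), np.asarray(pair[1])
    if np.sum((a - a.mean()) ** 2) == 0:
        return
    m = metrics(a, p)
    n = len(a)
    assert m.r2 == pytest.approx(
        1.0 - m.rmse**2 * n / np.sum((a - a.mean()) ** 2), rel=1e-6, abs=1e-9
    )


class TestRmAnova:
    def test_two_conditions_f_equals_paired_t_squared(self):
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((6, 2)) + [0.0, 0.4]
        res = rm_anova(Y)
        t, p = stats.ttest_rel(Y[:, 0], Y[:, 1])
        assert res["F"] == pytest.approx(t**2, rel=1e-9)
        assert res["p"] == pytest.approx(p, rel=1e-9)

    def test_identical_columns_give_zero_f(self):
        rng = np.random.default_rng(1)
        col = rng.standard_normal(8)
        res = rm_anova(np.column_stack([col, col, col]))
        assert res["F"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        n, k = 10, 4
        Y = rng.standard_normal((n, k)) + np.arange(k) * 0.3
        res = rm_anova(Y)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "cond": np.tile(np.arange(k), n),
                "y": Y.ravel(),
            }
        )
        out = pg.rm_anova(data=df, dv="y", within="cond", subject="subject")
        pcol = "p_unc" if "p_unc" in out.columns else "p-unc"
        assert res["F"] == pytest.approx(float(out["F"].iloc[0]), rel=1e-6)
        assert res["p"] == pytest.approx(float(out[pcol].iloc[0]), rel=1e-6)


def _fake_report(k_models=4, n=8, seed=0, identical=False):
    rng = np.random.default_rng(seed)
    names = tuple(f"m{i}" for i in range(k_models))
    base = rng.uniform(0.5, 0.9, n)
    values = {}
    for i, m in enumerate(names):
        col = base if identical else base + 0.05 * i + 0.01 * rng.standard_normal(n)
        values[m] = {metric: col.copy() for metric in METRIC_ORDER}
    return EvalReport(model_names=names, n_repeats=n, values=values)


class TestCompareModels:
    def test_bonferroni_count_and_scaling(self):
        rep = _fake_report()
        out = compare_models(rep)
        for metric in METRIC_ORDER:
            pw = out[metric]["pairwise"]
            assert len(pw) == 6  # 4 models -> 6 pairs
            for row in pw:
                assert row["p_adj"] == pytest.approx(min(1.0, row["p_raw"] * 6))
                assert row["p_adj"] >= row["p_raw"]

    def test_identical_models_not_significant(self):
        out = compare_models(_fake_report(identical=True))
        for metric in METRIC_ORDER:
            assert out[metric]["anova"]["F"] == pytest.approx(0.0, abs=1e-9)
            for row in out[metric]["pairwise"]:
                assert row["p_adj"] == 1.0

    def test_ci_contains_mean(self):
        out = compare_models(_fake_report(seed=5))
        for metric in METRIC_ORDER:
            for ci in out[metric]["ci"].values():
                assert ci["lo"] <= ci["mean"] <= ci["hi"]


class TestRunExperiment:
    def test_structure_and_determinism(self, small_table):
        specs = {
            "mean": lambda t, s: _mean_model(t),
            "noisy": lambda t, s: _noisy_mean_model(t, s),
        }
        r1 = run_experiment(small_table, specs, n_repeats=3, seed=11)
        r2 = run_experiment(small_table, specs, n_repeats=3, seed=11)
        assert r1.to_dict() == r2.to_dict()
        assert len(r1.values["mean"]["rmse"]) == 3

    def test_harness_metrics_match_stored_predictions(self, small_table):
        specs = {"mean": lambda t, s: _mean_model(t)}
        rep = run_experiment(small_table, specs, n_repeats=2, seed=3)
        for r, (y_true, y_pred) in enumerate(rep.predictions["mean"]):
            m = metrics(y_true, y_pred)
            for k in METRIC_ORDER:
                assert rep.values["mean"][k][r] == pytest.approx(getattr(m, k))

    def test_summary_shape(self, small_table):
        specs = {"mean": lambda t, s: _mean_model(t)}
        rep = run_experiment(small_table, specs, n_repeats=2, seed=0)
        summary = rep.summary()
        assert list(summary["model"]) == ["mean"]
        assert "r2_mean" in summary.columns and "rmse_sd" in summary.columns


def _mean_model(table):
    """Predicts the training-label mean (a valid degenerate regressor)."""
    from strengthsense.models import TrainedModel

    h = 1
    d = table.X.shape[1]
    w = np.zeros(d * h + h + h + 1)
    w[-1] = float(np.mean(table.y))
    return TrainedModel(kind="bpnn", n_features=d, params={"weights": w, "hidden_size": h})


def _noisy_mean_model(table, seed):
    from strengthsense.models import TrainedModel

    rng = np.random.default_rng(seed)
    h, d = 1, table.X.shape[1]
    w = np.zeros(d * h + h + h + 1)
    w[-1] = float(np.mean(table.y)) + 0.01 * rng.standard_normal()
    return TrainedModel(kind="bpnn", n_features=d, params={"weights": w, "hidden_size": h})
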