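"""Regression metrics, the repeated-run experiment harness, and model comparison.

Metrics (grade units unless noted):

* ``R^2  = 1 - sum((a - p)^2) / sum((a - mean(a))^2)`` — fit quality.
* ``RMSE = sqrt(mean((a - p)^2))`` — error magnitude, penalizing outliers.
* ``MAE  = mean(|a - p|)`` — average error magnitude.
* ``MBE  = mean(a - p)`` — signed bias. Note the sign convention: with
  this definition a *negative* MBE means the model over-predicts. A flag
  flips the sign for the opposite convention.

The harness repeats the whole train/test protocol with fresh seeded 7:3
splits, trains every model on identical partitions, and reports each
metric as mean +/- SD over repeats, followed by a one-way repeated-measures
ANOVA (models as the within factor, repeats as subjects) with
Bonferroni-corrected pairwise paired t-tests and 95% t-intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import FeatureTable, SplitSpec, apply_norm, fit_norm, split
from .models import (
    BpnnConfig,
    PsoConfig,
    predict,
    train_bpnn,
    train_pso_bpnn,
    train_pso_svr,
    train_svr,
    SvrConfig,
    DEFAULT_SVR_BOUNDS,
)

__all__ = [
    "MetricSet",
    "EvalReport",
    "metrics",
    "default_model_specs",
    "run_experiment",
    "compare_models",
    "MODEL_ORDER",
    "METRIC_ORDER",
]

MODEL_ORDER = ("bpnn", "svr", "pso_bpnn", "pso_svr")
METRIC_ORDER = ("r2", "rmse", "mae", "mbe")


@dataclass(frozen=True)
class MetricSet:
    """The four regression metrics for one prediction vector."""

    r2: float
    rmse: float
    mae: float
    mbe: float

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_ORDER}


def metrics(actual: np.ndarray, predicted: np.ndarray, flip_mbe: bool = False) -> MetricSet:
    """Evaluate R^2, RMSE, MAE and MBE.

    MBE is ``mean(actual - predicted)``; pass ``flip_mbe`` for the
    predicted-minus-actual convention.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.size == 0:
        raise ValueError("actual and predicted must be equal-length, non-empty")
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined for constant actual values")
    resid = a - p
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    mbe = float(np.mean(resid))
    if flip_mbe:
        mbe = -mbe
    return MetricSet(r2=r2, rmse=rmse, mae=mae, mbe=mbe)


@dataclass
class EvalReport:
    """Per-model, per-repeat metrics with stored prediction vectors."""

    model_names: tuple
    n_repeats: int
    #: values[model][metric] -> array over repeats
    values: dict
    #: predictions[model] -> list of (y_true, y_pred) per repeat
    predictions: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Mean +/- SD per model per metric (the comparison-table shape)."""
        rows = []
        for m in self.model_names:
            row = {"model": m}
            for metric in METRIC_ORDER:
                v = self.values[m][metric]
                row[f"{metric}_mean"] = float(np.mean(v))
                row[f"{metric}_sd"] = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "model_names": list(self.model_names),
            "n_repeats": self.n_repeats,
            "values": {
                m: {k: list(map(float, v)) for k, v in self.values[m].items()}
                for m in self.model_names
            },
            "summary": self.summary().to_dict(orient="records"),
        }


def default_model_specs(
    bpnn_cfg: BpnnConfig | None = None,
    svr_cfg: SvrConfig | None = None,
    svr_bounds: tuple = DEFAULT_SVR_BOUNDS,
    pso_svr_iters: int = 100,
    pso_svr_particles: int = 10,
    pso_bpnn_iters: int = 100,
    pso_bpnn_particles: int = 5,
) -> dict:
    """The four standard trainers, each a callable (table, seed) -> model.

    Configurations follow the study defaults: BPNN with 5 hidden units and
    1000 epochs; SVR with C=10, gamma=0.1, epsilon=0.1; PSO-SVR with 10
    particles, 100 iterations, c1=c2=1.7; PSO-BPNN with 5 particles, 100
    iterations, c1=c2=4.494.
    """
    bpnn_cfg = bpnn_cfg or BpnnConfig()
    svr_cfg = svr_cfg or SvrConfig()

    def bpnn(table, seed):
        return train_bpnn(table, BpnnConfig(**{**bpnn_cfg.__dict__, "seed": seed}))

    def svr(table, seed):
        return train_svr(table, svr_cfg)

    def pso_svr(table, seed):
        cfg = PsoConfig(
            bounds=svr_bounds,
            n_particles=pso_svr_particles,
            n_iters=pso_svr_iters,
            c1=1.7,
            c2=1.7,
            seed=seed,
        )
        return train_pso_svr(table, svr_bounds, cfg, epsilon=svr_cfg.epsilon)

    def pso_bpnn(table, seed):
        return train_pso_bpnn(
            table,
            BpnnConfig(**{**bpnn_cfg.__dict__, "seed": seed}),
            pso_cfg=None if (pso_bpnn_iters, pso_bpnn_particles) == (100, 5) else _pso_bpnn_cfg(
                table, bpnn_cfg, pso_bpnn_iters, pso_bpnn_particles, seed
            ),
        )

    return {"bpnn": bpnn, "svr": svr, "pso_bpnn": pso_bpnn, "pso_svr": pso_svr}


def _pso_bpnn_cfg(table, bpnn_cfg, n_iters, n_particles, seed):
    from .models import _bpnn_n_weights

    nw = _bpnn_n_weights(table.X.shape[1], bpnn_cfg.hidden_size)
    return PsoConfig(
        bounds=tuple((-2.0, 2.0) for _ in range(nw)),
        n_particles=n_particles,
        n_iters=n_iters,
        c1=4.494,
        c2=4.494,
        seed=seed,
    )


def _fan_out_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-repeat seeds below 2**31 from one master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n) % (2**31)


def run_experiment(
    table: FeatureTable,
    model_specs: dict | None = None,
    n_repeats: int = 10,
    seed: int = 0,
    train_fraction: float = 0.7,
    norm_on_all: bool = False,
    clip_grades: bool = False,
) -> EvalReport:
    """Repeat the full split/normalize/train/test protocol and collect metrics.

    Every repeat draws a fresh seeded 7:3 split; all models see identical
    partitions; normalization is fitted on the training rows (or on all
    rows with ``norm_on_all``).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if model_specs is None:
        model_specs = default_model_specs()
    names = tuple(model_specs)
    repeat_seeds = _fan_out_seeds(seed, n_repeats)

    values = {m: {k: [] for k in METRIC_ORDER} for m in names}
    predictions = {m: [] for m in names}
    for r in range(n_repeats):
        rseed = int(repeat_seeds[r])
        train, test = split(table, SplitSpec(train_fraction=train_fraction, seed=rseed))
        if norm_on_all:
            state = fit_norm(table.X, table.column_names)
        else:
            state = fit_norm(train.X, train.column_names)
        train_n = FeatureTable(
            X=apply_norm(train.X, state),
            y=train.y,
            subject_ids=train.subject_ids,
            column_names=train.column_names,
        )
        Xte = apply_norm(test.X, state)
        for m in names:
            model = model_specs[m](train_n, rseed)
            pred = predict(model, Xte, clip_grades=clip_grades)
            ms = metrics(test.y, pred)
            for k in METRIC_ORDER:
                values[m][k].append(getattr(ms, k))
            predictions[m].append((test.y.copy(), pred))

    values = {m: {k: np.array(v) for k, v in values[m].items()} for m in names}
    return EvalReport(
        model_names=names,
        n_repeats=n_repeats,
        values=values,
        predictions=predictions,
        seeds={"master": seed, "repeats": repeat_seeds.tolist()},
    )


# ---------------------------------------------------------------------------
# Statistical comparison
# ---------------------------------------------------------------------------

def rm_anova(Y: np.ndarray) -> dict:
    """One-way repeated-measures ANOVA from first-principles sums of squares.

    ``Y`` is (n_subjects, k_models). Returns F, p and the SS/df table.
    Sphericity correction is not applied.
    """
    Y = np.asarray(Y, dtype=float)
    n, k = Y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    grand = Y.mean()
    ss_models = n * np.sum((Y.mean(axis=0) - grand) ** 2)
    ss_subjects = k * np.sum((Y.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_error = ss_total - ss_models - ss_subjects
    df_models = k - 1
    df_error = (k - 1) * (n - 1)
    ms_models = ss_models / df_models
    ms_error = ss_error / df_error
    # guard against roundoff: both sums vanish when models are identical
    eps = 1e-12 * max(1.0, float(ss_total))
    if ms_error <= eps:
        F = 0.0 if ms_models <= eps else np.inf
    else:
        F = ms_models / ms_error
    p = float(stats.f.sf(F, df_models, df_error)) if np.isfinite(F) else 0.0
    return {
        "F": float(F),
        "p": p,
        "df_models": df_models,
        "df_error": df_error,
        "ss_models": float(ss_models),
        "ss_subjects": float(ss_subjects),
        "ss_error": float(ss_error),
    }


def compare_models(report: EvalReport, alpha: float = 0.05) -> dict:
    """ANOVA + Bonferroni pairwise tests + 95% CIs for every metric.

    Pairwise paired t-tests get the Bonferroni multiplier m = k(k-1)/2
    (adjusted p capped at 1). CIs are Student-t intervals over repeats.
    """
    names = report.model_names
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 models to compare")
    if report.n_repeats < 3:
        raise ValueError("need at least 3 paired observations")
    m_pairs = k * (k - 1) // 2
    out = {}
    for metric in METRIC_ORDER:
        Y = np.column_stack([report.values[m][metric] for m in names])
        anova = rm_anova(Y)
        pairwise = []
        for i in range(k):
            for j in range(i + 1, k):
                d = Y[:, i] - Y[:, j]
                if np.allclose(d, 0.0):
                    t_stat, p_raw = 0.0, 1.0
                else:
                    t_stat, p_raw = stats.ttest_rel(Y[:, i], Y[:, j])
                p_adj = min(1.0, float(p_raw) * m_pairs)
                pairwise.append(
                    {
                        "a": names[i],
                        "b": names[j],
                        "t": float(t_stat),
                        "p_raw": float(p_raw),
                        "p_adj": p_adj,
                        "significant": p_adj < alpha,
                    }
                )
        cis = {}
        n = report.n_repeats
        tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
        for m in names:
            v = report.values[m][metric]
            mean = float(np.mean(v))
            half = float(tcrit * np.std(v, ddof=1) / np.sqrt(n))
            cis[m] = {"mean": mean, "lo": mean - half, "hi": mean + half}
        out[metric] = {"anova": anova, "pairwise": pairwise, "ci": cis}
    return out
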