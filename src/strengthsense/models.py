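"""The four strength regressors: BPNN, SVR, PSO-BPNN and PSO-SVR.

* BPNN — a single-hidden-layer feedforward network (5 tanh units, linear
  output) trained by full-batch gradient backpropagation on squared error.
* SVR — epsilon-insensitive support vector regression with an RBF kernel
  (C = 10, gamma = 0.1, epsilon = 0.1 by default); samples inside the
  epsilon tube incur no loss.
* PSO-SVR — particle swarm search over (C, gamma) minimizing five-fold
  cross-validated RMSE on the training partition, then a final refit at
  the swarm optimum.
* PSO-BPNN — particle swarm search over the flattened network weight
  vector minimizing training MSE, followed by backpropagation fine-tuning
  from the swarm optimum (global search + local descent).

All trainers are seed-deterministic end to end, and ``predict`` is a pure
function of the trained model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVR as _SkSVR

from .dataset import FeatureTable, SplitSpec, kfold
from .optimize_pso import PsoConfig, pso_optimize

__all__ = [
    "BpnnConfig",
    "SvrConfig",
    "TrainedModel",
    "train_bpnn",
    "train_svr",
    "train_pso_svr",
    "train_pso_bpnn",
    "predict",
    "save_model",
    "load_model",
    "DEFAULT_SVR_BOUNDS",
]

#: Practical tuning box for the PSO-SVR search: C in [1, 100], gamma in [0.001, 1].
DEFAULT_SVR_BOUNDS = ((1.0, 100.0), (0.001, 1.0))


@dataclass(frozen=True)
class BpnnConfig:
    """Network and optimizer settings for the backpropagation regressor."""

    hidden_size: int = 5
    max_iter: int = 1000
    learning_rate: float = 0.01
    init_scale: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.hidden_size < 1 or self.max_iter < 1:
            raise ValueError("hidden_size and max_iter must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class SvrConfig:
    """RBF-kernel SVR hyperparameters."""

    C: float = 10.0
    gamma: float = 0.1
    epsilon: float = 0.1
    tol: float = 1e-6

    def __post_init__(self):
        if self.C <= 0 or self.gamma <= 0 or self.epsilon < 0:
            raise ValueError("require C > 0, gamma > 0, epsilon >= 0")


@dataclass
class TrainedModel:
    """A fitted regressor: kind, parameters, and training metadata.

    ``params`` holds plain arrays/scalars only, so models serialize to
    JSON and predictions are reproducible without the training code path.
    """

    kind: str
    n_features: int
    params: dict
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# BPNN: forward pass, gradients, training loop
# ---------------------------------------------------------------------------

def _bpnn_shapes(d: int, h: int):
    return [(d, h), (h,), (h,), ()]


def _bpnn_n_weights(d: int, h: int) -> int:
    return d * h + h + h + 1


def _unflatten(w: np.ndarray, d: int, h: int):
    W1 = w[: d * h].reshape(d, h)
    b1 = w[d * h : d * h + h]
    W2 = w[d * h + h : d * h + 2 * h]
    b2 = w[-1]
    return W1, b1, W2, b2


def _flatten(W1, b1, W2, b2) -> np.ndarray:
    return np.concatenate([W1.ravel(), b1, W2, [b2]])


def _bpnn_forward(w: np.ndarray, X: np.ndarray, d: int, h: int) -> np.ndarray:
    W1, b1, W2, b2 = _unflatten(w, d, h)
    return np.tanh(X @ W1 + b1) @ W2 + b2


def _bpnn_grad(w: np.ndarray, X: np.ndarray, y: np.ndarray, d: int, h: int):
    """MSE and its gradient w.r.t. the flattened weights (full batch)."""
    W1, b1, W2, b2 = _unflatten(w, d, h)
    Z = X @ W1 + b1
    A = np.tanh(Z)
    yhat = A @ W2 + b2
    err = yhat - y
    n = len(y)
    mse = float(np.mean(err**2))
    dyhat = 2.0 * err / n
    gW2 = A.T @ dyhat
    gb2 = np.sum(dyhat)
    dA = np.outer(dyhat, W2) * (1.0 - A**2)
    gW1 = X.T @ dA
    gb1 = dA.sum(axis=0)
    return mse, _flatten(gW1, gb1, gW2, gb2)


def _bpnn_descend(
    w0: np.ndarray, X: np.ndarray, y: np.ndarray, d: int, h: int, cfg: BpnnConfig
):
    """Fixed-rate full-batch gradient descent; returns the best-seen weights.

    Keeping the best-seen iterate guarantees the final training MSE never
    exceeds the starting MSE (monitored descent).
    """
    w = w0.copy()
    best_w = w.copy()
    best_mse = _bpnn_grad(w, X, y, d, h)[0]
    for _ in range(cfg.max_iter):
        mse, g = _bpnn_grad(w, X, y, d, h)
        if not np.isfinite(mse):
            raise FloatingPointError("BPNN training diverged to non-finite loss")
        if mse < best_mse:
            best_mse, best_w = mse, w.copy()
        w = w - cfg.learning_rate * g
    final_mse, _ = _bpnn_grad(w, X, y, d, h)
    if final_mse < best_mse:
        best_mse, best_w = final_mse, w.copy()
    return best_w, float(best_mse)


def _bpnn_init(rng: np.random.Generator, d: int, h: int, scale: float):
    """Standard random initialization of all weights and biases."""
    return rng.normal(scale=scale, size=_bpnn_n_weights(d, h))


def train_bpnn(table: FeatureTable, cfg: BpnnConfig = BpnnConfig()) -> TrainedModel:
    """Train the single-hidden-layer network on (already normalized) features.

    Plain error backpropagation from a random start: sensitive to the
    initialization, which is exactly the weakness the swarm-initialized
    variant addresses.
    """
    X, y = table.X, table.y
    d, h = X.shape[1], cfg.hidden_size
    rng = np.random.default_rng(cfg.seed)
    w0 = _bpnn_init(rng, d, h, cfg.init_scale)
    w, mse = _bpnn_descend(w0, X, y, d, h, cfg)
    return TrainedModel(
        kind="bpnn",
        n_features=d,
        params={"weights": w, "hidden_size": h},
        meta={"config": cfg.__dict__ | {}, "train_mse": mse},
    )


# ---------------------------------------------------------------------------
# SVR
# ---------------------------------------------------------------------------

def _fit_svr_params(X: np.ndarray, y: np.ndarray, cfg: SvrConfig) -> dict:
    sk = _SkSVR(kernel="rbf", C=cfg.C, gamma=cfg.gamma, epsilon=cfg.epsilon, tol=cfg.tol)
    sk.fit(X, y)
    return {
        "support_vectors": sk.support_vectors_.copy(),
        "dual_coef": sk.dual_coef_.ravel().copy(),
        "intercept": float(sk.intercept_[0]),
        "gamma": float(cfg.gamma),
    }


def _svr_predict(params: dict, X: np.ndarray) -> np.ndarray:
    sv = params["support_vectors"]
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(sv**2, axis=1)[None, :]
        - 2.0 * X @ sv.T
    )
    K = np.exp(-params["gamma"] * d2)
    return K @ params["dual_coef"] + params["intercept"]


def train_svr(table: FeatureTable, cfg: SvrConfig = SvrConfig()) -> TrainedModel:
    """Fit epsilon-insensitive RBF SVR at fixed hyperparameters."""
    params = _fit_svr_params(table.X, table.y, cfg)
    return TrainedModel(
        kind="svr",
        n_features=table.X.shape[1],
        params=params,
        meta={"config": cfg.__dict__ | {}},
    )


def _cv_rmse_svr(
    X: np.ndarray, y: np.ndarray, cfg: SvrConfig, folds: list
) -> float:
    """Mean RMSE over held-out folds for one (C, gamma) candidate."""
    rmses = []
    for te in folds:
        tr = np.setdiff1d(np.arange(len(y)), te)
        params = _fit_svr_params(X[tr], y[tr], cfg)
        pred = _svr_predict(params, X[te])
        rmses.append(np.sqrt(np.mean((y[te] - pred) ** 2)))
    return float(np.mean(rmses))


def train_pso_svr(
    table: FeatureTable,
    svr_bounds: tuple = DEFAULT_SVR_BOUNDS,
    pso_cfg: PsoConfig | None = None,
    epsilon: float = 0.1,
    fitness: str = "cv",
    cv_folds: int = 5,
) -> TrainedModel:
    """PSO search over (C, gamma), then refit on the full training partition.

    ``fitness='cv'`` (default) scores a candidate by five-fold
    cross-validated RMSE on the training partition; ``fitness='train'``
    uses raw training RMSE (which tends to drive C to its upper bound).
    """
    if pso_cfg is None:
        pso_cfg = PsoConfig(bounds=svr_bounds, n_particles=10, n_iters=100, c1=1.7, c2=1.7)
    X, y = table.X, table.y
    if fitness == "cv":
        folds = kfold(len(y), SplitSpec(seed=pso_cfg.seed, folds=cv_folds))

        def objective(pos):
            cfg = SvrConfig(C=pos[0], gamma=pos[1], epsilon=epsilon)
            return _cv_rmse_svr(X, y, cfg, folds)

    elif fitness == "train":

        def objective(pos):
            cfg = SvrConfig(C=pos[0], gamma=pos[1], epsilon=epsilon)
            pred = _svr_predict(_fit_svr_params(X, y, cfg), X)
            return float(np.sqrt(np.mean((y - pred) ** 2)))

    else:
        raise ValueError(f"unknown fitness mode {fitness!r}")

    # seed the swarm with the stock configuration when it lies in the box:
    # the tuned optimum is then a minimum over a set containing the default
    default = np.array([SvrConfig().C, SvrConfig().gamma])
    x0 = default[None, :] if np.all((default >= pso_cfg.lo) & (default <= pso_cfg.hi)) else None
    gbest, gfit, trace = pso_optimize(objective, pso_cfg, x0=x0)
    best_cfg = SvrConfig(C=float(gbest[0]), gamma=float(gbest[1]), epsilon=epsilon)
    params = _fit_svr_params(X, y, best_cfg)
    return TrainedModel(
        kind="pso_svr",
        n_features=X.shape[1],
        params=params,
        meta={
            "config": best_cfg.__dict__ | {},
            "pso_trace": trace,
            "pso_gbest": gbest,
            "pso_gbest_fitness": gfit,
        },
    )


def train_pso_bpnn(
    table: FeatureTable,
    bpnn_cfg: BpnnConfig = BpnnConfig(),
    pso_cfg: PsoConfig | None = None,
    weight_bound: float = 0.5,
) -> TrainedModel:
    """PSO over the flattened weight vector, then backpropagation fine-tune.

    The swarm (population 5, 100 iterations, c1 = c2 = 4.494 by default)
    minimizes training MSE over the network's flattened weights;
    backpropagation then refines the swarm optimum locally.

    Search box: weights and hidden biases in [-weight_bound, weight_bound]
    (default 0.5, a few times the 1/sqrt(fan_in) initialization scale —
    larger boxes saturate the tanh units and kill both the search and the
    fine-tune gradients), and the output bias spanning the label range.
    The swarm is seeded with the standard random initialization the plain
    network would use, so the searched start is never worse than it.
    """
    X, y = table.X, table.y
    d, h = X.shape[1], bpnn_cfg.hidden_size
    nw = _bpnn_n_weights(d, h)
    if pso_cfg is None:
        bounds = [(-weight_bound, weight_bound)] * (nw - 1)
        y_lo, y_hi = float(np.min(y)), float(np.max(y))
        pad = 0.5 * max(y_hi - y_lo, 1.0)
        bounds.append((y_lo - pad, y_hi + pad))
        pso_cfg = PsoConfig(
            bounds=tuple(bounds),
            n_particles=5,
            n_iters=100,
            c1=4.494,
            c2=4.494,
            seed=bpnn_cfg.seed,
        )
    if pso_cfg.ndim != nw:
        raise ValueError(f"pso bounds must have {nw} dimensions, got {pso_cfg.ndim}")

    def objective(w):
        yhat = _bpnn_forward(w, X, d, h)
        return float(np.mean((yhat - y) ** 2))

    rng0 = np.random.default_rng(bpnn_cfg.seed)
    w_heur = _bpnn_init(rng0, d, h, bpnn_cfg.init_scale)
    gbest, gfit, trace = pso_optimize(objective, pso_cfg, x0=w_heur)
    w, mse = _bpnn_descend(gbest, X, y, d, h, bpnn_cfg)
    return TrainedModel(
        kind="pso_bpnn",
        n_features=d,
        params={"weights": w, "hidden_size": h},
        meta={
            "config": bpnn_cfg.__dict__ | {},
            "pso_trace": trace,
            "pso_gbest_fitness": gfit,
            "train_mse": mse,
        },
    )


# ---------------------------------------------------------------------------
# Prediction and persistence
# ---------------------------------------------------------------------------

def predict(model: TrainedModel, X: np.ndarray, clip_grades: bool = False) -> np.ndarray:
    """Deterministic predictions for normalized feature rows.

    Set ``clip_grades`` to clamp outputs to the MMT range [2, 5].
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"model expects {model.n_features} features, got {X.shape[1]}"
        )
    if model.kind in ("bpnn", "pso_bpnn"):
        yhat = _bpnn_forward(
            np.asarray(model.params["weights"], dtype=float),
            X,
            model.n_features,
            int(model.params["hidden_size"]),
        )
    elif model.kind in ("svr", "pso_svr"):
        params = {
            "support_vectors": np.asarray(model.params["support_vectors"], dtype=float),
            "dual_coef": np.asarray(model.params["dual_coef"], dtype=float),
            "intercept": float(model.params["intercept"]),
            "gamma": float(model.params["gamma"]),
        }
        yhat = _svr_predict(params, X)
    else:
        raise ValueError(f"unknown model kind {model.kind!r}")
    if clip_grades:
        yhat = np.clip(yhat, 2.0, 5.0)
    return yhat


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Serialize a trained model to versioned JSON (text, portable)."""
    path = Path(path)
    payload = {
        "format_version": 1,
        "kind": model.kind,
        "n_features": model.n_features,
        "params": _jsonify(model.params),
        "meta": _jsonify(model.meta),
    }
    path.write_text(json.dumps(payload))
    return path


def load_model(path: str | Path) -> TrainedModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != 1:
        raise ValueError("unsupported model file version")
    params = payload["params"]
    for key in ("weights", "support_vectors", "dual_coef"):
        if key in params:
            params[key] = np.asarray(params[key], dtype=float)
    return TrainedModel(
        kind=payload["kind"],
        n_features=int(payload["n_features"]),
        params=params,
        meta=payload["meta"],
    )
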