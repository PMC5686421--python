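"""L2-regularized log-linear ranker and the two transfer-learning trainers.

All systems share one convex base objective

    J(w, b) = (1/2) ||w||^2 + C * sum_i a_i * l(w, b; x_i, y_i)

with l the logistic negative log-likelihood, per-example weights ``a_i``
(all 1 except for instance-weighted transfer) and an unpenalized bias.
Small C means strong regularization.

Trainers:

* ``train_baseline`` — SourceOnly / TargetOnly: plain fit on one corpus.
* ``train_fsa``      — feature space augmentation: source and target vectors
  are mapped into a tripled space <general | source-specific |
  target-specific> and a single plain model is fitted on the union; new
  target-domain terms are scored through the target mapping.
* ``train_sds``      — supervised distant supervision: instance weighting
  with weight alpha = beta * (K / N) on every source example, so beta = 1
  equalizes the total source and target corpus weights.

``grid_search`` selects (C, beta) by cross-validated average precision on
the target training data, with the source set fully included in every
fold's training portion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .datatypes import ConfigurationError, TransferConfig

GRAD_TOL = 1e-6
MAX_ITER = 10_000


@dataclass
class LogLinearModel:
    weights: np.ndarray
    bias: float
    feature_space_tag: str = "plain"  # "plain" | "augmented"
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.bias):
            raise ValueError("model parameters must be finite")
        if self.feature_space_tag not in ("plain", "augmented"):
            raise ValueError(f"unknown feature_space_tag {self.feature_space_tag!r}")


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _log1pexp(z: np.ndarray) -> np.ndarray:
    """log(1 + exp(z)), overflow-safe."""
    out = np.empty_like(z, dtype=float)
    big = z > 35
    out[big] = z[big]
    out[~big] = np.log1p(np.exp(z[~big]))
    return out


def loglinear_objective(
    params: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    sample_weight: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Value and gradient of J at params = (w, b)."""
    w, b = params[:-1], params[-1]
    z = X @ w + b
    s = 2.0 * y - 1.0  # labels to +/-1
    losses = _log1pexp(-s * z)
    value = 0.5 * float(w @ w) + C * float(sample_weight @ losses)
    # d/dz of log1pexp(-s z) = -s * sigmoid(-s z)
    gz = C * sample_weight * (-s) * sigmoid(-s * z)
    grad = np.concatenate([w + X.T @ gz, [gz.sum()]])
    return value, grad


def _objective_hessian(
    params: np.ndarray, X: np.ndarray, y: np.ndarray, C: float, sample_weight: np.ndarray
) -> np.ndarray:
    w, b = params[:-1], params[-1]
    z = X @ w + b
    p = sigmoid(z)
    d = C * sample_weight * p * (1.0 - p)
    Xd = X * d[:, None]
    n_feat = X.shape[1]
    H = np.zeros((n_feat + 1, n_feat + 1))
    H[:n_feat, :n_feat] = X.T @ Xd + np.eye(n_feat)
    H[:n_feat, n_feat] = Xd.sum(axis=0)
    H[n_feat, :n_feat] = H[:n_feat, n_feat]
    H[n_feat, n_feat] = d.sum()
    return H


def _check_training_data(X: np.ndarray, y: np.ndarray) -> None:
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values in training data")
    classes = set(np.unique(y).tolist())
    if classes != {0, 1}:
        raise ValueError(f"training data must contain both classes, got labels {sorted(classes)}")


def train_loglinear(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    sample_weight: np.ndarray | None = None,
    tag: str = "plain",
) -> LogLinearModel:
    """Fit the L2 log-linear model by deterministic convex optimization from
    zero initialization (L-BFGS with a Newton polish to gradient max-norm
    <= 1e-6)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_training_data(X, y)
    if C <= 0:
        raise ConfigurationError("C must be positive")
    sw = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    x0 = np.zeros(X.shape[1] + 1)
    res = minimize(
        loglinear_objective,
        x0,
        args=(X, y, C, sw),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": MAX_ITER, "ftol": 1e-14, "gtol": GRAD_TOL / 10},
    )
    params = res.x
    _, g = loglinear_objective(params, X, y, C, sw)
    if np.max(np.abs(g)) > GRAD_TOL:
        res2 = minimize(
            loglinear_objective,
            params,
            args=(X, y, C, sw),
            jac=True,
            hess=lambda p, *a: _objective_hessian(p, X, y, C, sw),
            method="trust-exact",
            options={"maxiter": 200, "gtol": GRAD_TOL / 10},
        )
        params = res2.x
    return LogLinearModel(weights=params[:-1], bias=float(params[-1]), feature_space_tag=tag,
                          config={"C": C})


def fsa_augment(X: np.ndarray, domain: str) -> np.ndarray:
    """Map F-vectors into the tripled space <general | source | target>:
    source rows become <x, x, 0>, target rows <x, 0, x>."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.zeros_like(X)
    if domain == "source":
        out = np.hstack([X, X, Z])
    elif domain == "target":
        out = np.hstack([X, Z, X])
    else:
        raise ValueError(f"domain must be source|target, got {domain!r}")
    return out


def predict_scores(model: LogLinearModel, X: np.ndarray) -> np.ndarray:
    """Probability of the positive class for each row.  Augmented models map
    new (target-domain) inputs through the target mapping first."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.feature_space_tag == "augmented":
        if X.shape[1] * 3 != model.weights.shape[0]:
            raise ValueError(
                f"feature dimension {X.shape[1]} incompatible with augmented model of 3F={model.weights.shape[0]}"
            )
        X = fsa_augment(X, "target")
    elif X.shape[1] != model.weights.shape[0]:
        raise ValueError(f"feature dimension {X.shape[1]} != model dimension {model.weights.shape[0]}")
    return sigmoid(X @ model.weights + model.bias)


def train_baseline(which: str, X: np.ndarray, y: np.ndarray, C: float) -> LogLinearModel:
    """SourceOnly / TargetOnly: plain fit on the designated corpus only."""
    if which not in ("SourceOnly", "TargetOnly"):
        raise ConfigurationError(f"unknown baseline {which!r}")
    m = train_loglinear(X, y, C)
    m.config["system"] = which
    return m


def train_fsa(
    Xs: np.ndarray, ys: np.ndarray, Xt: np.ndarray, yt: np.ndarray, C: float
) -> LogLinearModel:
    """Feature-space-augmentation trainer: one plain fit on the union of
    augmented source and target examples."""
    Xs = np.asarray(Xs, dtype=float).reshape(len(ys), -1) if len(ys) else np.zeros((0, np.asarray(Xt).shape[1]))
    Xt = np.asarray(Xt, dtype=float)
    if len(ys) and Xs.shape[1] != Xt.shape[1]:
        raise ValueError("source and target must share the feature dimension F")
    Xa = np.vstack([fsa_augment(Xs, "source"), fsa_augment(Xt, "target")]) if len(ys) else fsa_augment(Xt, "target")
    ya = np.concatenate([ys, yt])
    m = train_loglinear(Xa, ya, C, tag="augmented")
    m.config["system"] = "ADS-fsa"
    return m


def train_sds(
    Xs: np.ndarray,
    ys: np.ndarray,
    Xt: np.ndarray,
    yt: np.ndarray,
    C: float,
    alpha: float | None = None,
    beta: float | None = None,
) -> LogLinearModel:
    """Supervised-distant-supervision trainer.

    Minimizes (1/2)||w||^2 + C [ alpha * sum(source losses) + sum(target
    losses) ].  Supply either ``alpha`` directly or ``beta`` from which
    alpha = beta * (K / N) is derived.
    """
    N, K = len(ys), len(yt)
    if N == 0 or K == 0:
        raise ConfigurationError(
            "SDS needs both corpora; with one corpus use train_baseline (SourceOnly/TargetOnly)"
        )
    if alpha is None:
        if beta is None:
            raise ConfigurationError("supply alpha or beta")
        alpha = beta * (K / N)
    if alpha <= 0:
        raise ConfigurationError("alpha must be positive")
    Xs = np.asarray(Xs, dtype=float)
    Xt = np.asarray(Xt, dtype=float)
    if Xs.shape[1] != Xt.shape[1]:
        raise ValueError("source and target must share the feature dimension F")
    X = np.vstack([Xs, Xt])
    y = np.concatenate([ys, yt])
    sw = np.concatenate([np.full(N, alpha), np.ones(K)])
    m = train_loglinear(X, y, C, sample_weight=sw)
    m.config.update({"system": "ADS-sds", "alpha": alpha, "beta": beta})
    return m


def sds_objective_value(
    model: LogLinearModel,
    Xs: np.ndarray,
    ys: np.ndarray,
    Xt: np.ndarray,
    yt: np.ndarray,
    C: float,
    alpha: float,
) -> float:
    """SDS objective evaluated at the model's parameters (for optimality
    checks)."""
    X = np.vstack([Xs, Xt])
    y = np.concatenate([ys, yt])
    sw = np.concatenate([np.full(len(ys), alpha), np.ones(len(yt))])
    params = np.concatenate([model.weights, [model.bias]])
    value, _ = loglinear_objective(params, np.asarray(X, float), np.asarray(y, float), C, sw)
    return value


def _stratified_folds(
    y: np.ndarray, folds: int, seed: int, repeats: int = 1
) -> list[tuple[np.ndarray, np.ndarray]]:
    from sklearn.model_selection import RepeatedStratifiedKFold

    rskf = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    return [(tr, va) for tr, va in rskf.split(np.zeros(len(y)), y)]


def grid_scores(
    system: str,
    Xs: np.ndarray,
    ys: np.ndarray,
    Xt: np.ndarray,
    yt: np.ndarray,
    cfg: TransferConfig,
) -> dict[tuple[float, float | None], float]:
    """Cross-validated average precision on the target training set for every
    grid point (C, beta); beta is None for systems without a beta grid.

    The source set is fully included in every fold's training portion.  Folds
    whose validation part lacks a positive (or any second class) are skipped
    with a warning.
    """
    from .evaluation import average_precision

    yt = np.asarray(yt)
    beta_grid: tuple = tuple(cfg.beta_grid) if system == "ADS-sds" else (None,)
    C_grid = tuple(cfg.C_grid)
    class_counts = np.bincount(yt.astype(int), minlength=2)
    if class_counts.min() < 2:
        raise ConfigurationError(
            "target training set needs >=2 examples of each class for stratified grid search"
        )
    n_folds = min(cfg.cv_folds, int(class_counts.min()))
    folds = _stratified_folds(yt, n_folds, cfg.seed, repeats=max(1, cfg.cv_repeats))

    table: dict[tuple[float, float | None], float] = {}
    for C in C_grid:
        for beta in beta_grid:
            fold_scores = []
            for tr, va in folds:
                Xtr, ytr = Xt[tr], yt[tr]
                Xva, yva = Xt[va], yt[va]
                if yva.sum() == 0:
                    warnings.warn("validation fold without positives skipped", stacklevel=2)
                    continue
                try:
                    model = _fit_system(system, Xs, ys, Xtr, ytr, C, beta)
                except ValueError:
                    # e.g. a single-class training fold for TargetOnly
                    warnings.warn("unfittable fold skipped", stacklevel=2)
                    continue
                scores = predict_scores(model, Xva)
                fold_scores.append(average_precision(yva, scores))
            if fold_scores:
                table[(C, beta)] = float(np.mean(fold_scores))
    if not table:
        raise ConfigurationError("grid search failed: no evaluable fold")
    return table


def select_from_grid(table: dict[tuple[float, float | None], float]) -> tuple[float, float | None]:
    """Argmax of CV score; ties break toward stronger regularization
    (smaller C), then smaller beta."""
    def key(item):
        (C, beta), score = item
        return (score, -C, -(beta if beta is not None else 0.0))

    return max(table.items(), key=key)[0]


def grid_search(
    system: str,
    Xs: np.ndarray,
    ys: np.ndarray,
    Xt: np.ndarray,
    yt: np.ndarray,
    cfg: TransferConfig,
) -> tuple[float, float | None]:
    """Select (C, beta) by cross-validated average precision on the target
    training set (see ``grid_scores``); ties break toward stronger
    regularization (smaller C), then smaller beta."""
    return select_from_grid(grid_scores(system, Xs, ys, Xt, yt, cfg))


def _fit_system(
    system: str,
    Xs: np.ndarray,
    ys: np.ndarray,
    Xt: np.ndarray,
    yt: np.ndarray,
    C: float,
    beta: float | None,
) -> LogLinearModel:
    if system == "SourceOnly":
        return train_baseline("SourceOnly", Xs, ys, C)
    if system == "TargetOnly":
        return train_baseline("TargetOnly", Xt, yt, C)
    if system == "ADS-fsa":
        return train_fsa(Xs, ys, Xt, yt, C)
    if system == "ADS-sds":
        return train_sds(Xs, ys, Xt, yt, C, beta=beta)
    raise ConfigurationError(f"unknown system {system!r}")


def train_system(
    system: str,
    Xs: np.ndarray,
    ys: np.ndarray,
    Xt: np.ndarray,
    yt: np.ndarray,
    cfg: TransferConfig,
) -> LogLinearModel:
    """Grid-search hyperparameters (where applicable) and fit the final model
    on the full training data."""
    if system == "SourceOnly" and len(yt) == 0:
        C, beta = cfg.C, None
    else:
        C, beta = grid_search(system, Xs, ys, Xt, yt, cfg)
    model = _fit_system(system, Xs, ys, Xt, yt, C, beta)
    model.config.update({"C": C, "beta": beta})
    return model


def model_to_dict(model: LogLinearModel) -> dict:
    return {
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "feature_space_tag": model.feature_space_tag,
        "config": {k: v for k, v in model.config.items()},
    }


def model_from_dict(d: dict) -> LogLinearModel:
    return LogLinearModel(
        weights=np.asarray(d["weights"], dtype=float),
        bias=float(d["bias"]),
        feature_space_tag=d["feature_space_tag"],
        config=dict(d.get("config", {})),
    )
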