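"""Gradient-boosted classification of BMI category from the pooled embeddings.

LightGBM supplies the boosting machinery; the objective is the regularized
logistic loss with L1 strength 1.2 and L2 strength 0.8 on the leaf weights.
Four classes are handled by one softmax objective (the two-class restriction
of which is the ordinary binary logistic form); one-vs-rest is available by
flag. Tree-count / learning-rate / leaf settings are exposed because no
canonical values exist for them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import lightgbm as lgb


@dataclass(frozen=True)
class GBMConfig:
    n_trees: int = 200
    learning_rate: float = 0.1
    num_leaves: int = 31
    min_child_samples: int = 20
    lambda_l1: float = 1.2
    lambda_l2: float = 0.8
    n_classes: int = 4
    one_vs_rest: bool = False
    # when False, the constant init score stays out of the first tree's
    # leaves, so leaf values are pure boosting increments (the theta that
    # the L1/L2 penalties act on)
    boost_from_average: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("need at least one tree")
        if self.lambda_l1 < 0 or self.lambda_l2 < 0:
            raise ValueError("regularization strengths must be non-negative")


def regularized_logistic_loss(
    p: np.ndarray,
    y: np.ndarray,
    theta: np.ndarray,
    lambda_1: float = 1.2,
    lambda_2: float = 0.8,
) -> float:
    """Negative log-likelihood + lambda_1 ||theta||_1 + lambda_2 ||theta||_2^2.

    `p` is either an (N,) vector of positive-class probabilities (binary
    form) or an (N, K) row-stochastic matrix (softmax generalization whose
    two-class restriction is the binary form). Probabilities at exactly
    0 or 1 are clipped to [1e-12, 1 - 1e-12] with a warning.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    theta = np.asarray(theta, dtype=float)
    if not np.isfinite(theta).all():
        raise ValueError("leaf weights must be finite")
    if ((p <= 0) | (p >= 1)).any():
        warnings.warn("probabilities at 0/1 clipped to 1e-12", stacklevel=2)
        p = np.clip(p, 1e-12, 1 - 1e-12)
    if p.ndim == 1:
        nll = -float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    else:
        nll = -float(np.sum(np.log(p[np.arange(len(y)), y])))
    return nll + lambda_1 * float(np.abs(theta).sum()) + lambda_2 * float((theta ** 2).sum())


@dataclass
class GBMModel:
    booster: object
    config: GBMConfig
    n_features: int

    def leaf_weights(self) -> np.ndarray:
        """All leaf output values of the fitted ensemble (the theta of the
        regularized objective)."""
        dump = self.booster.booster_.dump_model()
        vals: list[float] = []

        def walk(node):
            if "leaf_value" in node:
                vals.append(node["leaf_value"])
                return
            walk(node["left_child"])
            walk(node["right_child"])

        for tree in dump["tree_info"]:
            walk(tree["tree_structure"])
        return np.array(vals)


def fit_gbm(z: np.ndarray, y: np.ndarray, config: GBMConfig = GBMConfig()) -> GBMModel:
    """Fit the boosted ensemble on embeddings; deterministic given the seed."""
    z = np.asarray(z, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(z) != len(y):
        raise ValueError("Z rows must match label length")
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes to fit a classifier")
    params = dict(
        n_estimators=config.n_trees,
        learning_rate=config.learning_rate,
        num_leaves=config.num_leaves,
        min_child_samples=config.min_child_samples,
        reg_alpha=config.lambda_l1,
        reg_lambda=config.lambda_l2,
        # default objective: softmax multiclass, whose 2-class restriction is
        # the binary logistic form (LightGBM selects it from the label set)
        objective="multiclassova" if config.one_vs_rest else None,
        boost_from_average=config.boost_from_average,
        random_state=config.seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
    )
    clf = lgb.LGBMClassifier(**params)
    clf.fit(z, y, eval_set=[(z, y)], eval_metric="multi_logloss",
            callbacks=[lgb.log_evaluation(period=0)])
    return GBMModel(booster=clf, config=config, n_features=z.shape[1])


def predict_proba(model: GBMModel, z: np.ndarray) -> np.ndarray:
    """Row-stochastic class posteriors; argmax is the predicted category."""
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[1] != model.n_features:
        raise ValueError(
            f"expected N x {model.n_features} embeddings, got {z.shape}"
        )
    if z.shape[0] == 0:
        return np.empty((0, model.config.n_classes))
    with warnings.catch_warnings():
        # the sklearn wrapper warns about missing feature names on ndarray
        # input even though fitting also used an ndarray
        warnings.filterwarnings("ignore", message=".*valid feature names.*")
        proba = model.booster.predict_proba(z)
    if model.config.one_vs_rest:
        # one-vs-all sigmoids are not a distribution; normalize rows
        proba = proba / proba.sum(axis=1, keepdims=True)
    # map onto the full class set when training saw a subset
    if proba.shape[1] != model.config.n_classes:
        full = np.zeros((len(z), model.config.n_classes))
        for j, cls in enumerate(model.booster.classes_):
            full[:, int(cls)] = proba[:, j]
        proba = full
    return proba


def training_curve(model: GBMModel) -> list[float]:
    """Training multi-logloss per boosting iteration (non-increasing)."""
    res = model.booster.evals_result_
    key = next(iter(res))
    metric = next(iter(res[key]))
    return list(res[key][metric])


def save_gbm(model: GBMModel, path, extractor_hash: str | None = None) -> None:
    model.booster.booster_.save_model(str(path))
    manifest = {
        "config": asdict(model.config),
        "n_features": model.n_features,
        "extractor_checkpoint_sha256": extractor_hash,
    }
    with open(str(path) + ".json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
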