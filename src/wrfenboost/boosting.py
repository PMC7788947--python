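"""Gradient-boosted viability prediction and the Pearson fitness bridge.

The predictor is a gradient-boosted regression-tree ensemble: the
prediction for a sample is the sum of the scores of all K trees evaluated
on the selected gene columns, built stagewise so that the prediction after
t rounds equals the prediction after t-1 rounds plus the t-th tree's
contribution.  Tree construction is delegated to xgboost; this module owns
the gene-restriction wrapper, the additive-stagewise probes, seeding, and
the validation-Pearson fitness evaluated by the swarm optimiser.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import pearsonr

from .febpso import HyperparamSpace, decode

logger = logging.getLogger(__name__)

#: untuned baseline hyperparameters (library defaults, 100 rounds), kept
#: as the comparison point for swarm-tuned combinations
DEFAULT_PARAMS = {
    "learning_rate": 0.3,
    "gamma": 0.0,
    "max_depth": 6,
    "min_child_weight": 1,
    "subsample": 1.0,
    "colsample_bytree": 1.0,
    "lambda": 1.0,
    "iteration_times": 100,
}


@dataclass
class TrainedModel:
    """A fitted ensemble restricted to a named feature list."""

    booster: xgb.XGBRegressor | None  # None for the 0-round model
    features: list
    params: dict
    base_score: float
    seed: int

    @property
    def n_rounds(self) -> int:
        return 0 if self.booster is None else self.booster.n_estimators


def _xgb_params(params: dict, n_features: int) -> dict:
    p = dict(DEFAULT_PARAMS, **params)
    colsample = max(float(p["colsample_bytree"]), 1.0 / max(n_features, 1))
    return {
        "learning_rate": float(p["learning_rate"]),
        "gamma": float(p["gamma"]),
        "max_depth": int(p["max_depth"]),
        "min_child_weight": float(p["min_child_weight"]),
        "subsample": float(p["subsample"]),
        "colsample_bytree": colsample,
        "reg_lambda": float(p["lambda"]),
        "n_estimators": int(p["iteration_times"]),
    }


def fit(X: pd.DataFrame, y, features: list, params: dict | None = None, seed: int = 0) -> TrainedModel:
    """Train the boosted ensemble on the given feature columns.

    ``params`` uses the search-space naming (``lambda``,
    ``iteration_times``); omitted keys fall back to :data:`DEFAULT_PARAMS`.
    A colsample decoding to 0 is clamped to the one-feature minimum.
    """
    missing = [f for f in features if f not in X.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    y = np.asarray(y, float)
    if len(y) < 2:
        raise ValueError("need at least 2 training rows")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite viability target")
    base = float(np.mean(y))
    xp = _xgb_params(params or {}, len(features))
    if xp["n_estimators"] == 0:
        return TrainedModel(booster=None, features=list(features), params=xp, base_score=base, seed=seed)
    model = xgb.XGBRegressor(
        objective="reg:squarederror",
        tree_method="hist",
        base_score=base,
        random_state=seed,
        n_jobs=1,
        **xp,
    )
    model.fit(X[features], y)
    return TrainedModel(booster=model, features=list(features), params=xp, base_score=base, seed=seed)


def predict(model: TrainedModel, rows: pd.DataFrame, n_rounds: int | None = None) -> np.ndarray:
    """Predict viability; features are aligned by column name.

    ``n_rounds`` truncates the ensemble to its first t trees, exposing the
    additive stagewise structure (t=0 returns the constant base score).
    """
    missing = [f for f in model.features if f not in rows.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    if n_rounds == 0 or model.booster is None:
        return np.full(len(rows), model.base_score)
    X = rows[model.features]
    if n_rounds is None:
        return model.booster.predict(X).astype(float)
    return model.booster.predict(X, iteration_range=(0, n_rounds)).astype(float)


def fitness_of(
    position,
    space: HyperparamSpace,
    train: tuple[pd.DataFrame, np.ndarray],
    val: tuple[pd.DataFrame, np.ndarray],
    features: list,
    seed: int = 0,
) -> float:
    """Swarm fitness: validation Pearson of the model a position encodes.

    Decodes the bit string, fits on the training fold and returns
    Pearson(observed, predicted) on the validation fold.  A degenerate
    Pearson (constant predictions) maps to -1 so the swarm can still rank
    the particle.
    """
    params = decode(position, space)
    model = fit(train[0], train[1], features, params, seed=seed)
    pred = predict(model, val[0])
    yval = np.asarray(val[1], float)
    if np.std(pred) == 0 or np.std(yval) == 0:
        logger.warning("constant predictions on the validation fold: fitness -1")
        return -1.0
    r = pearsonr(yval, pred)[0]
    if not np.isfinite(r):
        logger.warning("non-finite validation Pearson: fitness -1")
        return -1.0
    return float(r)
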