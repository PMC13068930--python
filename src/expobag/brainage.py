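"""Normative brain-age regression on the healthy reference sample.

Candidate models (linear, ridge, SVR, random forest) at several grey-matter
granularities are tuned by nested cross-validation on 80% of the healthy
sample (inner folds choose hyperparameters; repeated outer folds give a
fold-wise error breakdown), validated on the untouched 20% hold-out, and the
candidate with the smallest hold-out MAE is selected and refitted on the
full healthy sample before being applied to the population.

The 80/20 split is stratified by age decile so both partitions span the age
range; features are standardized inside every fit using training-fold
statistics only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.metrics import mean_absolute_error
from sklearn.model_selection import GridSearchCV, KFold, RepeatedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from expobag.errors import DegenerateModelError, SchemaError

ALGORITHMS = ("linear", "ridge", "svr", "random_forest")

HEALTH_CRITERIA = (
    ("long_standing_illness", 0),
    ("diabetes", 0),
    ("stroke", 0),
    ("icd10_diagnosis", 0),
)


@dataclass(frozen=True)
class CVSpec:
    """Nested-CV layout; defaults follow the reference protocol
    (10 outer folds x 5 repeats, 10 inner folds, 20% hold-out)."""

    outer_folds: int = 10
    outer_repeats: int = 5
    inner_folds: int = 10
    holdout_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must be in (0, 1)")


def default_grid(algorithm: str) -> dict:
    """Small hyperparameter grids sized for single-CPU desk runs."""
    if algorithm == "linear":
        return {}
    if algorithm == "ridge":
        return {"model__alpha": np.logspace(-2, 3, 6).tolist()}
    if algorithm == "svr":
        return {"model__C": [1.0, 10.0], "model__epsilon": [0.1, 1.0]}
    if algorithm == "random_forest":
        return {"model__max_depth": [8, 16]}
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass(frozen=True)
class ModelCandidate:
    algorithm: str
    granularity: int
    grid: dict | None = None

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    @property
    def name(self) -> str:
        return f"{self.algorithm}_{self.granularity}"

    def hyperparameter_grid(self) -> dict:
        return default_grid(self.algorithm) if self.grid is None else self.grid


@dataclass
class ModelEvaluation:
    """Hold-out performance plus the nested-CV fold breakdown."""

    r: float
    mae: float
    fold_metrics: pd.DataFrame  # columns: repeat, fold, mae, r_pooled_repeat
    n_holdout: int
    best_params: dict


@dataclass
class FittedBrainAgeModel:
    pipeline: Pipeline
    candidate: ModelCandidate
    feature_names: list
    train_ids: pd.Index      # 80% split used for tuning (and bias correction)
    holdout_ids: pd.Index    # untouched 20%
    best_params: dict
    seed: int
    training_hash: str = ""

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return predict_age(self, features)

    def sidecar(self) -> dict:
        return {
            "algorithm": self.candidate.algorithm,
            "granularity": self.candidate.granularity,
            "hyperparameters": self.best_params,
            "n_features": len(self.feature_names),
            "training_hash": self.training_hash,
            "seed": self.seed,
        }


def select_healthy(participants: pd.DataFrame) -> pd.Index:
    """Participants passing every health-eligibility criterion.

    Mirrors a healthy-norm selection: no long-standing illness, no diabetes,
    no stroke history, no diagnosis on record, and good-or-better self-rated
    health (code >= 3 on the 1-4 scale).
    """
    required = [name for name, _ in HEALTH_CRITERIA] + ["self_rated_health"]
    missing = [c for c in required if c not in participants.columns]
    if missing:
        raise SchemaError(f"participants table missing eligibility flags: {missing}")
    ok = pd.Series(True, index=participants.index)
    for flag, good in HEALTH_CRITERIA:
        ok &= participants[flag] == good
    ok &= participants["self_rated_health"] >= 3
    return participants.index[ok]


def _make_estimator(algorithm: str, seed: int) -> Pipeline:
    if algorithm == "linear":
        model = LinearRegression()
    elif algorithm == "ridge":
        model = Ridge()
    elif algorithm == "svr":
        model = SVR()
    else:
        model = RandomForestRegressor(
            n_estimators=50, max_features="sqrt", random_state=seed, n_jobs=1
        )
    return Pipeline([("scale", StandardScaler()), ("model", model)])


def _tune(pipe: Pipeline, grid: dict, X, y, inner_folds: int, seed: int):
    if not grid:
        fitted = pipe.fit(X, y)
        return fitted, {}
    search = GridSearchCV(
        pipe,
        grid,
        cv=KFold(inner_folds, shuffle=True, random_state=seed),
        scoring="neg_mean_absolute_error",
        n_jobs=1,
        refit=True,
    )
    search.fit(X, y)
    return search.best_estimator_, search.best_params_


def train_candidate(
    features: pd.DataFrame,
    ages: pd.Series,
    candidate: ModelCandidate,
    cv: CVSpec,
    refit_on_all: bool = True,
    nested_breakdown: bool = True,
):
    """Tune, validate and (optionally) refit one brain-age candidate.

    Returns ``(FittedBrainAgeModel, ModelEvaluation)``.  Hyperparameters are
    chosen on inner folds of the 80% training split only; the reported
    ``mae``/``r`` come from the 20% hold-out, which no tuning step ever saw.
    """
    if not features.index.equals(ages.index):
        raise SchemaError("feature rows and age vector are not aligned")
    if features.isna().any().any():
        raise SchemaError("grey-matter features contain missing values")
    y = ages.to_numpy(dtype=float)
    if np.unique(y).size < 2:
        raise DegenerateModelError("need at least 2 distinct ages")

    # age-decile stratified 80/20 split
    deciles = pd.qcut(ages, q=10, labels=False, duplicates="drop")
    train_ids, hold_ids = train_test_split(
        features.index,
        test_size=cv.holdout_fraction,
        random_state=cv.seed,
        stratify=deciles,
    )
    X_tr = features.loc[train_ids].to_numpy(dtype=float)
    y_tr = ages.loc[train_ids].to_numpy(dtype=float)
    X_ho = features.loc[hold_ids].to_numpy(dtype=float)
    y_ho = ages.loc[hold_ids].to_numpy(dtype=float)

    grid = candidate.hyperparameter_grid()
    rows = []
    if nested_breakdown:
        outer = RepeatedKFold(
            n_splits=cv.outer_folds, n_repeats=cv.outer_repeats, random_state=cv.seed
        )
        preds = {rep: (np.empty_like(y_tr), np.zeros(len(y_tr), dtype=bool)) for rep in range(cv.outer_repeats)}
        for split_idx, (tr, te) in enumerate(outer.split(X_tr)):
            rep, fold = divmod(split_idx, cv.outer_folds)
            est, _ = _tune(
                _make_estimator(candidate.algorithm, cv.seed),
                grid, X_tr[tr], y_tr[tr], cv.inner_folds, cv.seed,
            )
            p = est.predict(X_tr[te])
            preds[rep][0][te] = p
            preds[rep][1][te] = True
            rows.append({"repeat": rep, "fold": fold, "mae": mean_absolute_error(y_tr[te], p)})
        for rep in range(cv.outer_repeats):
            p, seen = preds[rep]
            r_rep = pearsonr(y_tr[seen], p[seen])[0]
            for row in rows:
                if row["repeat"] == rep:
                    row["r_pooled_repeat"] = r_rep
    fold_metrics = pd.DataFrame(rows)

    final_est, best_params = _tune(
        _make_estimator(candidate.algorithm, cv.seed), grid, X_tr, y_tr, cv.inner_folds, cv.seed
    )
    p_ho = final_est.predict(X_ho)
    evaluation = ModelEvaluation(
        r=float(pearsonr(y_ho, p_ho)[0]) if np.std(p_ho) > 0 else 0.0,
        mae=float(mean_absolute_error(y_ho, p_ho)),
        fold_metrics=fold_metrics,
        n_holdout=len(y_ho),
        best_params=best_params,
    )

    if refit_on_all:
        pipe = _make_estimator(candidate.algorithm, cv.seed)
        pipe.set_params(**best_params)
        pipe.fit(features.to_numpy(dtype=float), y)
    else:
        pipe = final_est

    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X_tr).tobytes())
    h.update(np.ascontiguousarray(y_tr).tobytes())
    model = FittedBrainAgeModel(
        pipeline=pipe,
        candidate=candidate,
        feature_names=list(features.columns),
        train_ids=pd.Index(train_ids),
        holdout_ids=pd.Index(hold_ids),
        best_params=best_params,
        seed=cv.seed,
        training_hash=h.hexdigest(),
    )
    return model, evaluation


def select_best_model(evaluations: list) -> ModelCandidate:
    """Pick the candidate with minimum hold-out MAE.

    Ties break by higher hold-out r, then lexicographically by candidate
    name, so selection is deterministic.
    """
    if not evaluations:
        raise ValueError("no candidates to select from")
    return min(evaluations, key=lambda ce: (ce[1].mae, -ce[1].r, ce[0].name))[0]


def predict_age(model: FittedBrainAgeModel, features: pd.DataFrame) -> np.ndarray:
    """One finite predicted age per row; columns must match training schema."""
    if list(features.columns) != model.feature_names:
        raise SchemaError(
            "feature columns do not match the training schema "
            f"({len(features.columns)} vs {len(model.feature_names)} columns)"
        )
    pred = model.pipeline.predict(features.to_numpy(dtype=float))
    if not np.all(np.isfinite(pred)):
        raise DegenerateModelError("non-finite age predictions")
    return pred


def save_model_sidecar(model: FittedBrainAgeModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.sidecar(), fh, indent=1)
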