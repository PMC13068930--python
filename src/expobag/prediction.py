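"""Exposome-based prediction of grey-matter health (BAG) under nested CV.

Every preprocessing statistic — confound-regression coefficients,
standardization means/scales, tuned hyperparameters — is estimated on
training-fold rows only and then applied, frozen, to the test fold.  The
outer repeated k-fold loop estimates generalization; an inner k-fold grid
search chooses hyperparameters.  Significance is assessed by permuting the
target and re-running the cross-validation (null distribution per metric),
and p-values across metrics are adjusted with Benjamini-Hochberg FDR.

Rows are sorted by participant id on entry, so results are invariant to the
row order of the input tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.model_selection import GridSearchCV, KFold, RepeatedKFold
from sklearn.svm import SVR

from expobag.errors import (
    ConditioningError,
    DegenerateModelError,
    SchemaError,
)

METRICS = ("mae", "mse", "rmse", "r2", "pearson_r")
# "at least as good as observed" means >= for fit metrics, <= for error metrics
GREATER_IS_BETTER = frozenset({"r2", "pearson_r"})

CONFOUND_COLUMNS = ("age", "age_squared", "sex", "height", "volumetric_scaling")


def confound_matrix(participants: pd.DataFrame) -> pd.DataFrame:
    """The standard confound set: age, age^2, sex, height, volumetric scaling."""
    missing = [c for c in ("age", "sex", "height", "volumetric_scaling") if c not in participants.columns]
    if missing:
        raise SchemaError(f"participants table missing confound columns: {missing}")
    out = pd.DataFrame(
        {
            "age": participants["age"],
            "age_squared": participants["age"] ** 2,
            "sex": participants["sex"],
            "height": participants["height"],
            "volumetric_scaling": participants["volumetric_scaling"],
        },
        index=participants.index,
    )
    return out


@dataclass(frozen=True)
class PredictionCVSpec:
    outer_folds: int = 5
    outer_repeats: int = 5
    inner_folds: int = 5
    algorithm: str = "random_forest"
    seed: int = 0
    param_grid: dict | None = None
    rf_n_estimators: int = 40

    def __post_init__(self):
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.algorithm not in ("random_forest", "ridge", "svr"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    def grid(self) -> dict:
        if self.param_grid is not None:
            return self.param_grid
        if self.algorithm == "random_forest":
            return {"max_depth": [6, 12]}
        if self.algorithm == "ridge":
            return {"alpha": np.logspace(-2, 3, 6).tolist()}
        return {"C": [1.0, 10.0], "epsilon": [0.1, 1.0]}


@dataclass(frozen=True)
class PermutationConfig:
    n_permutations: int = 500
    folds: int = 5
    seed: int = 0
    retune: bool = False

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")


@dataclass
class FoldArtifact:
    """Everything a fold's training data determined, frozen for audit."""

    repeat: int
    fold: int
    train_ids: np.ndarray
    test_ids: np.ndarray
    confound_beta: np.ndarray
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    best_params: dict
    model: object
    predictions: np.ndarray


@dataclass
class PredictionRun:
    fold_metrics: pd.DataFrame  # repeat, fold, mae, mse, rmse, r2, pearson_r
    metric_means: dict
    pooled_r_per_repeat: list
    predictions: pd.DataFrame  # participants x repeats
    artifacts: list
    cv: PredictionCVSpec
    feature_names: list

    def consensus_params(self) -> dict:
        """Most frequently tuned hyperparameters across outer folds."""
        counts = {}
        for a in self.artifacts:
            key = tuple(sorted(a.best_params.items()))
            counts[key] = counts.get(key, 0) + 1
        best = max(counts.items(), key=lambda kv: (kv[1], kv[0]))[0]
        return dict(best)


def _make_estimator(spec: PredictionCVSpec, seed: int):
    if spec.algorithm == "random_forest":
        return RandomForestRegressor(
            n_estimators=spec.rf_n_estimators,
            max_features="sqrt",
            random_state=seed,
            n_jobs=1,
        )
    if spec.algorithm == "ridge":
        return Ridge()
    return SVR()


def _fit_confound_model(C_train: np.ndarray) -> tuple:
    """Design and pseudo-inverse pieces for intercept-including confound OLS."""
    design = np.column_stack([np.ones(len(C_train)), C_train])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ConditioningError(
            f"confound design is rank deficient ({rank} < {design.shape[1]})"
        )
    return design


def remove_confounds(
    X: pd.DataFrame,
    confounds: pd.DataFrame,
    train_ids,
    apply_ids,
) -> pd.DataFrame:
    """Residualize exposome variables against confounds, leakage safe.

    For every column of ``X`` an intercept-including linear model on the
    confounds is fitted using **training rows only**; residuals are returned
    for the apply rows using those frozen coefficients.
    """
    train_ids = pd.Index(train_ids)
    apply_ids = pd.Index(apply_ids)
    X_tr = X.loc[train_ids].to_numpy(dtype=float)
    C_tr = confounds.loc[train_ids].to_numpy(dtype=float)
    design_tr = _fit_confound_model(C_tr)
    beta, *_ = np.linalg.lstsq(design_tr, X_tr, rcond=None)
    C_ap = confounds.loc[apply_ids].to_numpy(dtype=float)
    design_ap = np.column_stack([np.ones(len(C_ap)), C_ap])
    resid = X.loc[apply_ids].to_numpy(dtype=float) - design_ap @ beta
    return pd.DataFrame(resid, index=apply_ids, columns=X.columns)


def _preprocess_fold(Xv, Cv, train_idx, apply_idx):
    """Residualize then standardize, all statistics from train rows."""
    design_tr = np.column_stack([np.ones(len(train_idx)), Cv[train_idx]])
    if np.linalg.matrix_rank(design_tr) < design_tr.shape[1]:
        raise ConditioningError("confound design is rank deficient on training fold")
    beta, *_ = np.linalg.lstsq(design_tr, Xv[train_idx], rcond=None)

    def residualize(idx):
        design = np.column_stack([np.ones(len(idx)), Cv[idx]])
        return Xv[idx] - design @ beta

    R_tr = residualize(train_idx)
    mean = R_tr.mean(axis=0)
    scale = R_tr.std(axis=0)
    scale[scale == 0] = 1.0
    Z_tr = (R_tr - mean) / scale
    Z_ap = (residualize(apply_idx) - mean) / scale
    return Z_tr, Z_ap, beta, mean, scale


def _fold_scores(y_true, y_pred) -> dict:
    err = y_true - y_pred
    mse = float(np.mean(err**2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot > 0 else np.nan
    r = float(pearsonr(y_true, y_pred)[0]) if np.std(y_pred) > 0 and np.std(y_true) > 0 else 0.0
    return {
        "mae": float(np.mean(np.abs(err))),
        "mse": mse,
        "rmse": float(np.sqrt(mse)),
        "r2": r2,
        "pearson_r": r,
    }


def run_prediction(
    X: pd.DataFrame,
    y: pd.Series,
    confounds: pd.DataFrame,
    cv: PredictionCVSpec,
) -> PredictionRun:
    """Repeated nested CV predicting BAG from curated exposome variables.

    ``X`` must be complete-case (post curation).  Returns fold-wise metrics,
    per-repeat pooled correlations, per-participant predictions and the
    frozen per-fold artifacts (confound coefficients, scaler statistics,
    tuned hyperparameters, fitted models) used downstream for permutation
    re-runs and Shapley explanation.
    """
    if X.isna().any().any():
        raise SchemaError("exposome matrix must be complete-case; curate first")
    if not (X.index.equals(y.index) and X.index.equals(confounds.index)):
        raise SchemaError("X, y and confounds must share an aligned participant index")
    if len(X) < cv.outer_folds * 2:
        raise SchemaError("too few rows for the outer fold count")

    order = np.argsort(X.index.to_numpy(), kind="stable")
    X = X.iloc[order]
    y = y.iloc[order]
    confounds = confounds.iloc[order]
    yv = y.to_numpy(dtype=float)
    if np.std(yv) == 0:
        raise DegenerateModelError("constant target: BAG has zero variance")
    Xv = X.to_numpy(dtype=float)
    Cv = confounds.to_numpy(dtype=float)

    outer = RepeatedKFold(n_splits=cv.outer_folds, n_repeats=cv.outer_repeats, random_state=cv.seed)
    grid = cv.grid()
    rows, artifacts = [], []
    preds = np.full((len(X), cv.outer_repeats), np.nan)
    for split_idx, (tr, te) in enumerate(outer.split(Xv)):
        rep, fold = divmod(split_idx, cv.outer_folds)
        Z_tr, Z_te, beta, mean, scale = _preprocess_fold(Xv, Cv, tr, te)
        est = _make_estimator(cv, cv.seed)
        if grid:
            search = GridSearchCV(
                est,
                grid,
                cv=KFold(cv.inner_folds, shuffle=True, random_state=cv.seed),
                scoring="neg_mean_absolute_error",
                n_jobs=1,
            )
            search.fit(Z_tr, yv[tr])
            model, best_params = search.best_estimator_, search.best_params_
        else:
            model, best_params = est.fit(Z_tr, yv[tr]), {}
        p = model.predict(Z_te)
        preds[te, rep] = p
        scores = _fold_scores(yv[te], p)
        rows.append({"repeat": rep, "fold": fold, **scores})
        artifacts.append(
            FoldArtifact(
                repeat=rep,
                fold=fold,
                train_ids=X.index.to_numpy()[tr],
                test_ids=X.index.to_numpy()[te],
                confound_beta=beta,
                scaler_mean=mean,
                scaler_scale=scale,
                best_params=best_params,
                model=model,
                predictions=p,
            )
        )
    fold_metrics = pd.DataFrame(rows)
    pooled = [
        float(pearsonr(yv, preds[:, rep])[0]) for rep in range(cv.outer_repeats)
    ]
    return PredictionRun(
        fold_metrics=fold_metrics,
        metric_means={m: float(fold_metrics[m].mean()) for m in METRICS},
        pooled_r_per_repeat=pooled,
        predictions=pd.DataFrame(
            preds, index=X.index, columns=[f"repeat_{r}" for r in range(cv.outer_repeats)]
        ),
        artifacts=artifacts,
        cv=cv,
        feature_names=list(X.columns),
    )


def make_null_runner(
    X: pd.DataFrame,
    confounds: pd.DataFrame,
    cv: PredictionCVSpec,
    config: PermutationConfig,
    fixed_params: dict | None = None,
):
    """Build the CV re-run used for each permutation.

    In the default reduced-cost mode the tuned hyperparameters from the
    unpermuted run are frozen (``fixed_params``); with ``config.retune`` the
    inner grid search is repeated under every permutation.
    """
    order = np.argsort(X.index.to_numpy(), kind="stable")
    Xv = X.iloc[order].to_numpy(dtype=float)
    Cv = confounds.iloc[order].to_numpy(dtype=float)
    kf = KFold(config.folds, shuffle=True, random_state=config.seed)
    splits = list(kf.split(Xv))
    grid = cv.grid()

    def run_fn(y_perm: np.ndarray) -> dict:
        fold_rows = []
        for tr, te in splits:
            Z_tr, Z_te, *_ = _preprocess_fold(Xv, Cv, tr, te)
            est = _make_estimator(cv, cv.seed)
            if config.retune and grid:
                search = GridSearchCV(
                    est, grid,
                    cv=KFold(cv.inner_folds, shuffle=True, random_state=cv.seed),
                    scoring="neg_mean_absolute_error", n_jobs=1,
                )
                search.fit(Z_tr, y_perm[tr])
                model = search.best_estimator_
            else:
                if fixed_params:
                    est.set_params(**fixed_params)
                model = est.fit(Z_tr, y_perm[tr])
            fold_rows.append(_fold_scores(y_perm[te], model.predict(Z_te)))
        return {m: float(np.mean([fr[m] for fr in fold_rows])) for m in METRICS}

    run_fn.order = order
    return run_fn


def permutation_test(
    run_fn,
    y: pd.Series,
    observed: dict,
    config: PermutationConfig,
):
    """Permutation p-values per metric.

    ``run_fn(y_shuffled)`` recomputes the cross-validated metric means under
    one target shuffle.  p = (1 + #{null at least as good}) / (B + 1), where
    "at least as good" means >= for r/r-squared and <= for error metrics, so
    the smallest attainable p is 1/(B+1) (~0.002 at B = 500).
    """
    rng = np.random.default_rng(config.seed)
    yv = y.to_numpy(dtype=float) if hasattr(y, "to_numpy") else np.asarray(y, dtype=float)
    order = getattr(run_fn, "order", None)
    if order is not None:
        yv = yv[order]
    nulls = []
    for _ in range(config.n_permutations):
        nulls.append(run_fn(rng.permutation(yv)))
    null_df = pd.DataFrame(nulls)
    p = {}
    for m in METRICS:
        if m not in observed:
            continue
        null_vals = null_df[m].to_numpy()
        if m in GREATER_IS_BETTER:
            b = int(np.sum(null_vals >= observed[m]))
        else:
            b = int(np.sum(null_vals <= observed[m]))
        p[m] = (1 + b) / (config.n_permutations + 1)
    return p, null_df


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, clipped at 1.

    q for the i-th smallest p is ``min_{j >= i} p_(j) * m / j``; the adjusted
    values are monotone non-decreasing in p-rank.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def summarize_metrics(
    run: PredictionRun,
    p_values: dict | None = None,
) -> pd.DataFrame:
    """Per-metric summary (mean, sd over folds, permutation p, BH q)."""
    rows = []
    for m in METRICS:
        rows.append(
            {
                "metric": m,
                "mean": run.metric_means[m],
                "sd": float(run.fold_metrics[m].std(ddof=1)),
            }
        )
    out = pd.DataFrame(rows).set_index("metric")
    if p_values:
        out["p"] = [p_values.get(m, np.nan) for m in out.index]
        mask = out["p"].notna()
        q = np.full(len(out), np.nan)
        q[mask.to_numpy()] = fdr_correct(out.loc[mask, "p"].to_numpy())
        out["q"] = q
    return out
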