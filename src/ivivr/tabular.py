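"""Tabular regression on the extracted feature table.

Eight model families (linear, LASSO, ridge, elastic net, random forest,
SVR, MLP and a deeper "DNN" perceptron), each grid-searched under seeded
10-fold cross-validation; polynomial feature engineering with greedy
removal of highly correlated columns; a predict-the-mean reference
baseline; and per-feature attribution of the best model (exact Shapley
values for additive-linear models, permutation importance otherwise).

Reported RMSE/R2 are pooled out-of-fold values (every record predicted
exactly once by a model that never saw it), stated as such in the result
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
from sklearn.model_selection import GridSearchCV, KFold, cross_val_predict
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.svm import SVR

ALGORITHMS = ("linear", "lasso", "ridge", "elasticnet", "random_forest",
              "svr", "mlp", "dnn")

_SCALED = {"linear", "lasso", "ridge", "elasticnet", "svr", "mlp", "dnn"}


def default_grid(algorithm: str) -> dict[str, list]:
    """Small documented hyperparameter grids per algorithm."""
    grids = {
        "linear": {"model__fit_intercept": [True, False]},
        "lasso": {"model__alpha": [1e-3, 1e-2, 1e-1, 1.0]},
        "ridge": {"model__alpha": [1e-2, 1e-1, 1.0, 10.0]},
        "elasticnet": {"model__alpha": [1e-3, 1e-2, 1e-1],
                       "model__l1_ratio": [0.2, 0.5, 0.8]},
        "random_forest": {"model__n_estimators": [100, 300],
                          "model__max_depth": [None, 5]},
        "svr": {"model__C": [1.0, 10.0, 100.0],
                "model__gamma": ["scale", 0.01]},
        "mlp": {"model__hidden_layer_sizes": [(32,), (64,)],
                "model__alpha": [1e-4, 1e-3]},
        "dnn": {"model__hidden_layer_sizes": [(64, 64), (64, 64, 32)],
                "model__alpha": [1e-4, 1e-3]},
    }
    return grids[algorithm]


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str
    hyperparameter_grid: Mapping[str, list] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.hyperparameter_grid is not None and not self.hyperparameter_grid:
            raise ValueError("hyperparameter grid must be non-empty")

    @property
    def grid(self) -> Mapping[str, list]:
        return self.hyperparameter_grid or default_grid(self.algorithm)


def _estimator(spec: ModelSpec) -> Pipeline:
    seed = spec.seed
    base = {
        "linear": LinearRegression(),
        "lasso": Lasso(max_iter=20000),
        "ridge": Ridge(),
        "elasticnet": ElasticNet(max_iter=20000),
        "random_forest": RandomForestRegressor(random_state=seed),
        "svr": SVR(),
        "mlp": MLPRegressor(max_iter=3000, random_state=seed),
        "dnn": MLPRegressor(max_iter=3000, random_state=seed,
                            hidden_layer_sizes=(64, 64)),
    }[spec.algorithm]
    steps = []
    if spec.algorithm in _SCALED:
        steps.append(("scale", StandardScaler()))
    steps.append(("model", base))
    return Pipeline(steps)


# ---------------------------------------------------------------------------
# feature engineering


@dataclass
class EngineeredTable:
    """Polynomially expanded feature table after correlation pruning."""

    frame: pd.DataFrame
    degree: int
    correlation_threshold: float
    dropped: list[str]
    generated: list[str]


def engineer_features(table: pd.DataFrame, degree: int = 2,
                      threshold: float = 0.95) -> EngineeredTable:
    """All monomials up to ``degree`` over the base columns, then greedy
    correlation pruning.

    Columns are scanned in order; a column is dropped when its absolute
    Pearson correlation with any *retained* earlier column exceeds the
    threshold.  Constant columns have undefined correlation and are
    retained.  Deterministic given column order.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if degree == 1:
        expanded = table.copy()
    else:
        poly = PolynomialFeatures(degree=degree, include_bias=False)
        values = poly.fit_transform(table.to_numpy())
        names = poly.get_feature_names_out(table.columns)
        expanded = pd.DataFrame(values, columns=names, index=table.index)
    X = expanded.to_numpy(dtype=float)
    n = X.shape[0]
    sd = X.std(axis=0)
    centred = X - X.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, centred / np.where(sd > 0, sd, 1.0), 0.0)
    kept_idx: list[int] = []
    dropped: list[str] = []
    kept_z: list[np.ndarray] = []
    for j in range(X.shape[1]):
        if sd[j] == 0:  # constant: correlation undefined, retain
            kept_idx.append(j)
            continue
        if kept_z:
            r = np.abs(np.stack(kept_z) @ z[:, j]) / n
            if threshold < 1 and np.any(r > threshold):
                dropped.append(expanded.columns[j])
                continue
        kept_idx.append(j)
        kept_z.append(z[:, j])
    return EngineeredTable(frame=expanded.iloc[:, kept_idx], degree=degree,
                           correlation_threshold=threshold, dropped=dropped,
                           generated=list(expanded.columns))


# ---------------------------------------------------------------------------
# fitting


@dataclass
class CVResult:
    algorithm: str
    best_params: dict
    predictions: np.ndarray  # pooled out-of-fold predictions, original order
    rmse: float
    r2: float
    model: Pipeline  # best configuration refit on all rows
    metadata: dict = field(default_factory=dict)


def fit_with_cv(spec: ModelSpec, table: pd.DataFrame,
                targets: Sequence[float], k: int = 10) -> CVResult:
    """Exhaustive grid search with seeded k-fold CV; returns the grid point
    minimising mean CV RMSE together with its pooled out-of-fold
    predictions and metrics."""
    from ivivr.evaluation import r_squared, rmse

    y = np.asarray(targets, dtype=float)
    X = table.to_numpy(dtype=float)
    if len(y) != len(X):
        raise ValueError("targets and table row counts differ")
    if k > len(y):
        raise ValueError(f"k={k} exceeds the {len(y)} available rows")
    cv = KFold(n_splits=k, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(_estimator(spec), dict(spec.grid), cv=cv,
                          scoring="neg_root_mean_squared_error", refit=True)
    search.fit(X, y)
    best = clone(_estimator(spec)).set_params(**search.best_params_)
    preds = cross_val_predict(best, X, y, cv=cv)
    result = CVResult(
        algorithm=spec.algorithm, best_params=dict(search.best_params_),
        predictions=preds, rmse=rmse(preds, y), r2=r_squared(preds, y),
        model=search.best_estimator_,
        metadata={"k": k, "seed": spec.seed,
                  "metric_pooling": "pooled out-of-fold"})
    return result


def reference_rmse(targets: Sequence[float]) -> tuple[float, float]:
    """The predict-the-mean baseline: (RMSE, R2); R2 is 0 by construction."""
    y = np.asarray(targets, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 targets")
    return float(np.sqrt(np.mean((y - y.mean()) ** 2))), 0.0


def leaderboard(table: pd.DataFrame, targets: Sequence[float],
                algorithms: Sequence[str] = ALGORITHMS, k: int = 10,
                seed: int = 0) -> tuple[pd.DataFrame, dict[str, CVResult]]:
    """Fit every algorithm and assemble an RMSE/R2 leaderboard with the
    reference baseline in the first column."""
    ref_rmse, ref_r2 = reference_rmse(targets)
    results = {a: fit_with_cv(ModelSpec(a, seed=seed), table, targets, k=k)
               for a in algorithms}
    board = pd.DataFrame({
        "Ref.": {"RMSE": ref_rmse, "R2": ref_r2},
        **{a: {"RMSE": r.rmse, "R2": r.r2} for a, r in results.items()},
    })
    return board, results


# ---------------------------------------------------------------------------
# attribution


def attribute_features(result: CVResult, table: pd.DataFrame,
                       targets: Sequence[float] | None = None,
                       mode: str = "auto", seed: int = 0,
                       top: int | None = None) -> pd.DataFrame:
    """Rank features of a fitted model by mean absolute impact.

    ``mode="shapley"`` computes exact per-record Shapley values for
    additive-linear models (impact_ij = coef_j * (x_ij - mean_j) in the
    model's standardised space), which satisfy local accuracy: per record
    the impacts sum to prediction minus baseline.  ``mode="permutation"``
    uses permutation importance (requires ``targets``); ``"auto"`` picks
    Shapley for linear-family models.
    Returns a DataFrame (feature, mean_abs_impact[, per-record columns])
    sorted descending.
    """
    model = result.model
    X = table.to_numpy(dtype=float)
    linear_family = result.algorithm in ("linear", "lasso", "ridge", "elasticnet")
    if mode == "auto":
        mode = "shapley" if linear_family else "permutation"
    if mode == "shapley":
        if not linear_family:
            raise ValueError("exact Shapley attribution supports the "
                             "additive-linear family only")
        scaler: StandardScaler = model.named_steps["scale"]
        lm = model.named_steps["model"]
        Xs = scaler.transform(X)
        impacts = lm.coef_ * (Xs - Xs.mean(axis=0))  # (n, p), signed
        mean_abs = np.abs(impacts).mean(axis=0)
        out = pd.DataFrame({"feature": table.columns,
                            "mean_abs_impact": mean_abs})
        out.attrs["impacts"] = impacts
        out.attrs["baseline"] = float(model.predict(X).mean())
    else:
        if targets is None:
            raise ValueError("permutation importance requires targets")
        imp = permutation_importance(model, X, np.asarray(targets, float),
                                     n_repeats=10, random_state=seed,
                                     scoring="neg_mean_squared_error")
        out = pd.DataFrame({"feature": table.columns,
                            "mean_abs_impact": np.abs(imp.importances_mean)})
    out = out.sort_values("mean_abs_impact", ascending=False,
                          kind="stable").reset_index(drop=True)
    return out.head(top) if top else out
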