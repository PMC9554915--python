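"""Estimator comparison protocol: grids, metrics, repeated evaluation.

Six regressors are compared on each radius-grid dataset: linear regression
(LR), Gaussian process regression (GPR), support vector regression (SVR),
k-nearest-neighbour regression (KNR), random forest (RF) and gradient
boosting (XGB).  LR/GPR/SVR/KNR receive standardized, elastic-net-selected
features; the tree ensembles consume the filtered features directly and
carry a max-depth grid of {3, 4, 5}.

Default protocol: per repetition a random 80/20 split; hyperparameters are
chosen on the 80% by exhaustive grid search minimising 5-fold CV MAE; the
winning pipeline is refitted on the full 80% and scored on the held-out 20%
(MAE, RMSE, R2, Spearman correlation).  Ten repetitions give mean ± sd per
metric; a true outer k-fold protocol is available as a switch.  Models are
compared pairwise per metric with the two-sided Mann–Whitney U test over
the per-repetition samples (significance at p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, WhiteKernel
from sklearn.linear_model import LinearRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .assembly import LABEL_COLUMN, StudyRecord, build_design_matrix, radius_grid
from .preprocessing import (
    ElasticNetSelector,
    FeatureStandardizer,
    TrainMeanImputer,
    VarianceCorrelationFilter,
)

ESTIMATOR_NAMES = ("LR", "GPR", "SVR", "KNR", "RF", "XGB")

#: Elastic-net hyperparameter grid shared by the standardized branch.
ELASTIC_NET_GRID = {"select__alpha": [10.0, 100.0], "select__rho": [0.5, 0.75, 1.0]}


@dataclass
class EstimatorSpec:
    """One regressor: factory, hyperparameter grid and preprocessing branch."""

    name: str
    factory: Callable[[int], object]
    grid: dict[str, list] = field(default_factory=dict)
    needs_standardization: bool = False
    uses_elastic_net: bool = False

    def make_pipeline(self, seed: int = 0) -> Pipeline:
        steps = [
            ("impute", TrainMeanImputer()),
            ("filter", VarianceCorrelationFilter()),
        ]
        if self.needs_standardization:
            steps.append(("scale", FeatureStandardizer()))
        if self.uses_elastic_net:
            steps.append(("select", ElasticNetSelector()))
        steps.append(("model", self.factory(seed)))
        return Pipeline(steps)

    def full_grid(self) -> dict[str, list]:
        grid = dict(self.grid)
        if self.uses_elastic_net:
            grid.update(ELASTIC_NET_GRID)
        return grid


def default_estimator_specs(n_jobs: int = 1) -> dict[str, EstimatorSpec]:
    """The six study estimators with their documented default grids."""
    return {
        "LR": EstimatorSpec(
            "LR", lambda seed: LinearRegression(),
            needs_standardization=True, uses_elastic_net=True,
        ),
        "GPR": EstimatorSpec(
            "GPR", lambda seed: GaussianProcessRegressor(
                kernel=RBF() + WhiteKernel(), normalize_y=True, random_state=seed,
            ),
            grid={"model__kernel": [
                RBF() + WhiteKernel(noise_level=nl)
                for nl in (1e-4, 1e-3, 1e-2, 1e-1, 1.0)
            ]},
            needs_standardization=True, uses_elastic_net=True,
        ),
        "SVR": EstimatorSpec(
            "SVR", lambda seed: SVR(kernel="rbf"),
            grid={"model__C": [0.1, 1.0, 10.0, 100.0],
                  "model__epsilon": [0.01, 0.1, 1.0]},
            needs_standardization=True, uses_elastic_net=True,
        ),
        "KNR": EstimatorSpec(
            "KNR", lambda seed: KNeighborsRegressor(),
            grid={"model__n_neighbors": [3, 5, 7, 9, 11],
                  "model__weights": ["uniform", "distance"]},
            needs_standardization=True, uses_elastic_net=True,
        ),
        "RF": EstimatorSpec(
            "RF", lambda seed: RandomForestRegressor(random_state=seed, n_jobs=n_jobs),
            grid={"model__n_estimators": [100, 300, 500],
                  "model__max_depth": [3, 4, 5]},
        ),
        "XGB": EstimatorSpec(
            "XGB", lambda seed: XGBRegressor(
                objective="reg:squarederror", random_state=seed,
                n_jobs=n_jobs, tree_method="hist", verbosity=0,
            ),
            grid={"model__learning_rate": [0.01, 0.05, 0.1],
                  "model__n_estimators": [100, 300, 500],
                  "model__max_depth": [3, 4, 5]},
        ),
    }


def compute_metrics(y_true, y_pred) -> dict[str, float]:
    """MAE and RMSE in mV, coefficient of determination, Spearman correlation."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("y_true and y_pred must be equal-length vectors of size >= 2")
    if np.ptp(y_true) == 0.0:
        raise ValueError("R2 undefined for constant y_true")
    diff = y_pred - y_true
    sc = stats.spearmanr(y_true, y_pred).statistic
    return {
        "MAE": float(mean_absolute_error(y_true, y_pred)),
        "RMSE": float(np.sqrt(np.mean(diff**2))),
        "R2": float(r2_score(y_true, y_pred)),
        "SC": float(sc),
    }


@dataclass
class ExperimentResult:
    """Per-repetition metrics for one estimator at one (r1, r2)."""

    estimator: str
    r1: float | None
    r2: float | None
    metrics: pd.DataFrame              # one row per repetition: MAE/RMSE/R2/SC
    chosen_params: list[dict]
    seeds: list[int]

    def summary(self) -> pd.DataFrame:
        """Mean and standard deviation per metric (Table-1 shape)."""
        return pd.DataFrame({"mean": self.metrics.mean(), "sd": self.metrics.std(ddof=1)})


def _repetition_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def inner_grid_search(
    X_train, y_train, spec: EstimatorSpec, k: int = 5, seed: int = 0,
    grid: dict | None = None,
) -> GridSearchCV:
    """Exhaustive grid search minimising k-fold CV MAE (ties: grid order).

    Preprocessing is part of the searched pipeline, so every fold refits
    imputation, filtering, scaling and selection on its own training part.
    """
    search_grid = spec.full_grid() if grid is None else grid
    search = GridSearchCV(
        spec.make_pipeline(seed),
        param_grid=search_grid,
        scoring="neg_mean_absolute_error",
        cv=KFold(n_splits=k, shuffle=True, random_state=seed),
        refit=True,
        n_jobs=1,
    )
    search.fit(X_train, y_train)
    return search


def repeated_evaluation(
    matrix: pd.DataFrame,
    spec: EstimatorSpec,
    n_repeats: int = 10,
    test_fraction: float = 0.2,
    seed: int = 0,
    cv_folds: int = 5,
    grid: dict | None = None,
    protocol: str = "repeated-split",
) -> ExperimentResult:
    """Repeated held-out evaluation of one estimator on one design matrix.

    ``protocol="repeated-split"`` (default): ``n_repeats`` random
    80/20 splits.  ``protocol="outer-kfold"``: one pass of an outer
    ``n_repeats``-fold CV, one repetition per fold.
    """
    X = matrix.drop(columns=[LABEL_COLUMN])
    y = matrix[LABEL_COLUMN]
    rep_seeds = _repetition_seeds(seed, n_repeats)
    if protocol == "repeated-split":
        splits = []
        for rep_seed in rep_seeds:
            tr, te = train_test_split(
                np.arange(len(X)), test_size=test_fraction, random_state=rep_seed
            )
            splits.append((tr, te))
    elif protocol == "outer-kfold":
        outer = KFold(n_splits=n_repeats, shuffle=True, random_state=seed)
        splits = list(outer.split(X))
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    rows, params = [], []
    for (train_idx, test_idx), rep_seed in zip(splits, rep_seeds):
        X_train, X_test = X.iloc[train_idx], X.iloc[test_idx]
        y_train, y_test = y.iloc[train_idx], y.iloc[test_idx]
        search = inner_grid_search(X_train, y_train, spec, cv_folds, rep_seed, grid)
        y_pred = search.predict(X_test)
        rows.append(compute_metrics(y_test, y_pred))
        params.append(search.best_params_)
    return ExperimentResult(
        estimator=spec.name,
        r1=matrix.attrs.get("r1"),
        r2=matrix.attrs.get("r2"),
        metrics=pd.DataFrame(rows),
        chosen_params=params,
        seeds=rep_seeds,
    )


def radius_scan(
    records: list[StudyRecord],
    spec: EstimatorSpec,
    grid_points: list[tuple[float, float]] | None = None,
    n_repeats: int = 10,
    seed: int = 0,
    param_grid: dict | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, dict[tuple[float, float], ExperimentResult]]:
    """Mean test MAE of one estimator over the (r1, r2) grid.

    Returns a (r1 × r2) matrix of mean MAE plus the per-configuration
    results; the argmin configuration is stored in ``mae.attrs["argmin"]``.
    """
    grid_points = grid_points or radius_grid()
    results: dict[tuple[float, float], ExperimentResult] = {}
    for r1, r2 in grid_points:
        matrix = build_design_matrix(records, r1, r2)
        results[(r1, r2)] = repeated_evaluation(
            matrix, spec, n_repeats=n_repeats, seed=seed, grid=param_grid, **kwargs
        )
    r1s = sorted({p[0] for p in grid_points})
    r2s = sorted({p[1] for p in grid_points})
    mae = pd.DataFrame(index=pd.Index(r1s, name="r1"),
                       columns=pd.Index(r2s, name="r2"), dtype=float)
    for (r1, r2), res in results.items():
        mae.loc[r1, r2] = res.metrics["MAE"].mean()
    stacked = mae.stack()
    mae.attrs["argmin"] = tuple(stacked.idxmin())
    return mae, results


@dataclass
class ComparisonReport:
    """Pairwise Mann–Whitney U p-values per metric, flags at p < 0.05."""

    metric: str
    p_values: pd.DataFrame
    significant: pd.DataFrame
    alpha: float = 0.05


def mann_whitney_p(x, y) -> float:
    """Two-sided Mann–Whitney U p-value; identical constant samples give 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(np.concatenate([x, y])) == 0.0:
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def pairwise_model_comparison(
    results: list[ExperimentResult], metric: str = "MAE", alpha: float = 0.05
) -> ComparisonReport:
    """Two-sided Mann–Whitney U over per-repetition metric samples, all pairs."""
    if len(results) < 2:
        raise ValueError("need at least two results to compare")
    n_reps = {len(r.metrics) for r in results}
    if len(n_reps) != 1:
        raise ValueError("results have unequal repetition counts")
    names = [r.estimator for r in results]
    p = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(results):
        for j, b in enumerate(results):
            if i < j:
                pv = mann_whitney_p(a.metrics[metric], b.metrics[metric])
                p.iloc[i, j] = p.iloc[j, i] = pv
    return ComparisonReport(metric=metric, p_values=p, significant=p < alpha, alpha=alpha)


def results_to_tidy(results: list[ExperimentResult]) -> pd.DataFrame:
    """Tidy long-format frame: estimator × (r1,r2) × repetition × metric."""
    rows = []
    for res in results:
        for rep, (_, metrics) in enumerate(res.metrics.iterrows()):
            for metric, value in metrics.items():
                rows.append({
                    "estimator": res.estimator, "r1": res.r1, "r2": res.r2,
                    "repetition": rep, "metric": metric, "value": value,
                })
    return pd.DataFrame(rows)
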