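"""Additive (Shapley-value) feature attribution for fitted models.

A fitted model ``f`` is explained by per-sample, per-feature attributions
``φ_{i,j}`` (in mV) plus a base value ``φ₀`` such that for every sample
``φ₀ + Σ_j φ_{i,j} = f(x_i)`` (local accuracy).  Three routes:

* **linear models** — closed form: ``φ_{i,j} = w_j (x_{i,j} − μ_j)`` with
  ``μ`` the background feature means, ``φ₀ = w·μ + b``;
* **tree ensembles** — exact path-dependent tree attribution: for sklearn
  decision trees / random forests the polynomial-time TreeSHAP recursion is
  implemented here; XGBoost boosters use their native per-tree contribution
  predictor (the same algorithm);
* **anything else** — model-agnostic Shapley estimation against a background
  sample: exact subset enumeration for ≤13 features, otherwise a seeded
  kernel-weighted regression whose solution is constrained to satisfy local
  accuracy.

Feature relevance is ranked by mean absolute attribution, the ordering used
in summary/violin plots.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.pipeline import Pipeline
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

from .assembly import LABEL_COLUMN, StudyRecord, build_design_matrix
from .evaluation import EstimatorSpec, default_estimator_specs, inner_grid_search


@dataclass
class ShapExplanation:
    """Base value plus per-sample per-feature attribution matrix (mV)."""

    base_value: float
    values: np.ndarray            # shape (n_samples, n_features)
    feature_names: list[str]
    data: np.ndarray              # raw feature values, for plot coloring

    def check_local_accuracy(self, predictions: np.ndarray, tol: float = 1e-4) -> float:
        """Max |φ₀ + Σφ − f(x)| over samples; raises if above ``tol``."""
        recon = self.base_value + self.values.sum(axis=1)
        err = float(np.max(np.abs(recon - np.asarray(predictions, float))))
        if err > tol:
            raise AssertionError(f"local accuracy violated: max error {err:g} mV")
        return err

    def summary_frame(self) -> pd.DataFrame:
        """(feature, mean |φ|) in descending relevance order."""
        ranked = rank_features(self)
        return pd.DataFrame(ranked, columns=["feature", "mean_abs_shap"])

    def per_sample_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)


# ---------------------------------------------------------------------------
# Exact attribution for single decision trees (path-dependent recursion).

class _PathElement:
    __slots__ = ("d", "z", "o", "w")

    def __init__(self, d, z, o, w):
        self.d, self.z, self.o, self.w = d, z, o, w

    def copy(self):
        return _PathElement(self.d, self.z, self.o, self.w)


def _extend(path, p_zero, p_one, feature_index):
    length = len(path)
    path = [e.copy() for e in path]
    path.append(_PathElement(feature_index, p_zero, p_one, 1.0 if length == 0 else 0.0))
    for i in range(length - 1, -1, -1):
        path[i + 1].w += p_one * path[i].w * (i + 1) / (length + 1)
        path[i].w = p_zero * path[i].w * (length - i) / (length + 1)
    return path


def _unwind(path, index):
    length = len(path)
    one, zero = path[index].o, path[index].z
    path = [e.copy() for e in path]
    n = path[length - 1].w
    # the removed extension commutes to the top of the path, so the weight
    # recurrence is inverted over every position
    for j in range(length - 2, -1, -1):
        if one != 0.0:
            t = path[j].w
            path[j].w = n * length / ((j + 1) * one)
            n = t - path[j].w * zero * (length - (j + 1)) / length
        else:
            path[j].w = path[j].w * length / (zero * (length - (j + 1)))
    for j in range(index, length - 1):
        path[j].d, path[j].z, path[j].o = path[j + 1].d, path[j + 1].z, path[j + 1].o
    path.pop()
    return path


def _unwound_sum(path, index):
    return sum(e.w for e in _unwind(path, index))


@dataclass
class _TreeArrays:
    """Uniform array view of one regression tree (sklearn or xgboost)."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray                  # per-node leaf value
    cover: np.ndarray                  # per-node training weight
    strict_less: bool                  # True: go left iff x < t (xgboost)

    def goes_left(self, x_value: float, node: int) -> bool:
        if self.strict_less:
            return x_value < self.threshold[node]
        return x_value <= self.threshold[node]

    def expected_value(self) -> float:
        leaves = self.children_left < 0
        return float(np.sum(self.value[leaves] * self.cover[leaves]) / self.cover[0])

    def predict_one(self, x: np.ndarray) -> float:
        node = 0
        while self.children_left[node] >= 0:
            if self.goes_left(x[self.feature[node]], node):
                node = self.children_left[node]
            else:
                node = self.children_right[node]
        return float(self.value[node])


def _tree_shap_single(tree: _TreeArrays, x, phi):
    """Accumulate the exact path-dependent attributions of one tree."""
    left, right = tree.children_left, tree.children_right
    feature, value, cover = tree.feature, tree.value, tree.cover

    def recurse(node, path, p_zero, p_one, feature_index):
        path = _extend(path, p_zero, p_one, feature_index)
        if left[node] < 0:  # leaf
            for i in range(1, len(path)):
                w = _unwound_sum(path, i)
                phi[path[i].d] += w * (path[i].o - path[i].z) * value[node]
            return
        d = feature[node]
        hot, cold = (left[node], right[node]) if tree.goes_left(x[d], node) \
            else (right[node], left[node])
        i_zero = i_one = 1.0
        k = next((i for i in range(1, len(path)) if path[i].d == d), None)
        if k is not None:
            i_zero, i_one = path[k].z, path[k].o
            path = _unwind(path, k)
        recurse(hot, path, i_zero * cover[hot] / cover[node], i_one, d)
        recurse(cold, path, i_zero * cover[cold] / cover[node], 0.0, d)

    recurse(0, [], 1.0, 1.0, -1)


def _sklearn_tree_arrays(tree) -> _TreeArrays:
    return _TreeArrays(
        children_left=tree.children_left,
        children_right=tree.children_right,
        feature=tree.feature,
        threshold=tree.threshold,
        value=tree.value[:, 0, 0].astype(float),
        cover=tree.weighted_n_node_samples.astype(float),
        strict_less=False,
    )


def xgboost_tree_arrays(model: XGBRegressor) -> tuple[list[_TreeArrays], float]:
    """Parse a fitted booster into per-tree arrays plus the base score."""
    import json

    booster = model.get_booster()
    config = json.loads(booster.save_config())
    base_score = float(config["learner"]["learner_model_param"]["base_score"])
    frame = booster.trees_to_dataframe()
    name_to_idx = {n: i for i, n in enumerate(booster.feature_names or [])}
    trees = []
    for _, tf in frame.groupby("Tree", sort=True):
        tf = tf.sort_values("Node")
        id_to_node = {i: n for i, n in zip(tf["ID"], tf["Node"])}
        is_leaf = (tf["Feature"] == "Leaf").to_numpy()
        n = len(tf)
        left = np.full(n, -1, dtype=int)
        right = np.full(n, -1, dtype=int)
        feat = np.full(n, -1, dtype=int)
        thr = np.zeros(n)
        val = np.zeros(n)
        for row, leaf in zip(tf.itertuples(index=False), is_leaf):
            node = row.Node
            if leaf:
                val[node] = row.Gain  # leaf weight is reported in the Gain column
            else:
                left[node] = id_to_node[row.Yes]
                right[node] = id_to_node[row.No]
                feat[node] = name_to_idx.get(row.Feature, -1)
                if feat[node] < 0:
                    feat[node] = int(str(row.Feature).lstrip("f"))
                thr[node] = row.Split
        trees.append(_TreeArrays(
            children_left=left, children_right=right, feature=feat,
            # round-trip through float32 recovers the exact split bits
            threshold=thr.astype(np.float32).astype(float),
            value=val, cover=tf["Cover"].to_numpy(dtype=float),
            strict_less=True,
        ))
    return trees, base_score


def _explain_tree_ensemble(
    trees: list[_TreeArrays], X: np.ndarray, scale: float, offset: float
) -> tuple[float, np.ndarray]:
    phi = np.zeros((X.shape[0], X.shape[1]))
    base = offset
    for tree in trees:
        base += tree.expected_value() * scale
        for i in range(X.shape[0]):
            row_phi = np.zeros(X.shape[1])
            _tree_shap_single(tree, X[i], row_phi)
            phi[i] += row_phi * scale
    return base, phi


def explain_sklearn_trees(model, X: np.ndarray) -> tuple[float, np.ndarray]:
    """Exact attributions for a DecisionTreeRegressor or RandomForestRegressor."""
    if isinstance(model, DecisionTreeRegressor):
        trees, scale = [_sklearn_tree_arrays(model.tree_)], 1.0
    elif isinstance(model, RandomForestRegressor):
        trees = [_sklearn_tree_arrays(est.tree_) for est in model.estimators_]
        scale = 1.0 / len(trees)
    else:
        raise TypeError(f"unsupported tree model: {type(model).__name__}")
    # sklearn applies thresholds to float32-cast inputs
    X = np.asarray(X, dtype=np.float32).astype(float)
    return _explain_tree_ensemble(trees, X, scale, 0.0)


def explain_xgboost(model: XGBRegressor, X) -> tuple[float, np.ndarray]:
    """Exact float64 attributions over the parsed booster trees.

    The booster's own contribution predictor implements the same recursion
    in float32; recomputing it here in double precision keeps local
    accuracy tight on mV-scale outputs.  :func:`xgboost_predict_f64` is the
    matching double-precision evaluation of the fitted ensemble.
    """
    trees, base_score = xgboost_tree_arrays(model)
    X = np.asarray(X, dtype=np.float32).astype(float)
    return _explain_tree_ensemble(trees, X, 1.0, base_score)


def xgboost_predict_f64(model: XGBRegressor, X) -> np.ndarray:
    """Double-precision evaluation of a fitted booster (sum of leaf weights)."""
    trees, base_score = xgboost_tree_arrays(model)
    X = np.asarray(X, dtype=np.float32).astype(float)
    return np.array([
        base_score + sum(t.predict_one(row) for t in trees) for row in X
    ])


def explain_linear(model, X: np.ndarray, background: np.ndarray) -> tuple[float, np.ndarray]:
    """Closed-form attributions for a fitted linear model."""
    w = np.asarray(model.coef_, dtype=float).ravel()
    mu = np.asarray(background, dtype=float).mean(axis=0)
    phi = (np.asarray(X, float) - mu) * w
    base = float(w @ mu + model.intercept_)
    return base, phi


# ---------------------------------------------------------------------------
# Model-agnostic fallback.

def _shapley_exact(predict, x, background) -> tuple[float, np.ndarray]:
    p = x.shape[0]
    players = list(range(p))

    def v(subset: tuple[int, ...]) -> float:
        pts = background.copy()
        if subset:
            pts[:, list(subset)] = x[list(subset)]
        return float(np.mean(predict(pts)))

    cache: dict[tuple[int, ...], float] = {}

    def value(subset) -> float:
        key = tuple(sorted(subset))
        if key not in cache:
            cache[key] = v(key)
        return cache[key]

    phi = np.zeros(p)
    for j in players:
        others = [k for k in players if k != j]
        for r in range(p):
            weight = math.factorial(r) * math.factorial(p - r - 1) / math.factorial(p)
            for subset in itertools.combinations(others, r):
                phi[j] += weight * (value(subset + (j,)) - value(subset))
    return value(()), phi


def _shapley_sampled(predict, x, background, n_samples, rng) -> tuple[float, np.ndarray]:
    # kernel-weighted regression on random coalitions, with the full and
    # empty coalitions pinned so local accuracy holds by construction
    p = x.shape[0]
    base = float(np.mean(predict(background)))
    fx = float(np.mean(predict(x[None, :])))
    masks = rng.integers(0, 2, size=(n_samples, p), dtype=bool)
    keep = (masks.sum(axis=1) > 0) & (masks.sum(axis=1) < p)
    masks = masks[keep]
    vals = np.empty(len(masks))
    for i, mask in enumerate(masks):
        pts = background.copy()
        pts[:, mask] = x[mask]
        vals[i] = np.mean(predict(pts))
    sizes = masks.sum(axis=1)
    weights = (p - 1) / (sizes * (p - sizes))
    # solve weighted least squares with the efficiency constraint sum(phi) = fx - base
    Z = masks.astype(float)
    y = vals - base
    last = Z[:, -1]
    Zr = Z[:, :-1] - last[:, None]
    yr = y - last * (fx - base)
    W = np.diag(weights)
    beta, *_ = np.linalg.lstsq(np.sqrt(W) @ Zr, np.sqrt(W) @ yr, rcond=None)
    phi = np.append(beta, (fx - base) - beta.sum())
    return base, phi


def explain_sampling(model, X, background, seed: int = 0,
                     n_samples: int = 2048) -> tuple[float, np.ndarray]:
    """Shapley attribution for arbitrary regressors against a background.

    Exact subset enumeration for ≤13 features; otherwise seeded coalition
    sampling with a constrained kernel regression.
    """
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    rng = np.random.default_rng(seed)
    predict = lambda pts: np.asarray(model.predict(pts), dtype=float).ravel()
    phis, base = [], None
    for row in X:
        if X.shape[1] <= 13:
            base, phi = _shapley_exact(predict, row, background)
        else:
            base, phi = _shapley_sampled(predict, row, background, n_samples, rng)
        phis.append(phi)
    return float(base), np.vstack(phis)


# ---------------------------------------------------------------------------
# Dispatch, ranking, final-model workflow.

def explain(model, X, background=None, seed: int = 0,
            feature_names: list[str] | None = None) -> ShapExplanation:
    """Attribution for a fitted model over a feature matrix.

    ``X`` (and the optional ``background``, defaulting to ``X``) must carry
    the same columns the model was trained on; a DataFrame supplies the
    feature names.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X_arr = X.to_numpy(dtype=float)
    else:
        X_arr = np.asarray(X, dtype=float)
        feature_names = feature_names or [f"x{i}" for i in range(X_arr.shape[1])]
    n_expected = getattr(model, "n_features_in_", X_arr.shape[1])
    if X_arr.shape[1] != n_expected:
        raise ValueError(
            f"feature mismatch: model expects {n_expected}, got {X_arr.shape[1]}"
        )
    bg = X_arr if background is None else np.asarray(
        background.to_numpy(dtype=float) if isinstance(background, pd.DataFrame)
        else background, dtype=float,
    )
    if isinstance(model, XGBRegressor):
        base, phi = explain_xgboost(model, X_arr)
    elif isinstance(model, (DecisionTreeRegressor, RandomForestRegressor)):
        base, phi = explain_sklearn_trees(model, X_arr)
    elif hasattr(model, "coef_") and hasattr(model, "intercept_"):
        base, phi = explain_linear(model, X_arr, bg)
    else:
        base, phi = explain_sampling(model, X_arr, bg, seed=seed)
    return ShapExplanation(base_value=base, values=phi,
                           feature_names=list(feature_names), data=X_arr)


def rank_features(explanation: ShapExplanation) -> list[tuple[str, float]]:
    """Features by descending mean |φ|; exact ties fall back to name order."""
    mean_abs = np.mean(np.abs(explanation.values), axis=0)
    order = sorted(
        range(len(mean_abs)),
        key=lambda j: (-mean_abs[j], explanation.feature_names[j]),
    )
    return [(explanation.feature_names[j], float(mean_abs[j])) for j in order]


def final_model_explanation(
    records: list[StudyRecord],
    best_config: tuple[float, float] = (13.0, 3.0),
    seed: int = 0,
    spec: EstimatorSpec | None = None,
    grid: dict | None = None,
    cv_folds: int = 5,
) -> tuple[ShapExplanation, Pipeline]:
    """Refit the best estimator (XGB by default) on *all* records and explain it.

    The model is retrained on the entire dataset at the chosen radius
    configuration (hyperparameters re-searched by inner CV), then the
    per-sample attributions are computed over the same rows.
    """
    r1, r2 = best_config
    matrix = build_design_matrix(records, r1, r2)
    spec = spec or default_estimator_specs()["XGB"]
    X = matrix.drop(columns=[LABEL_COLUMN])
    y = matrix[LABEL_COLUMN]
    search = inner_grid_search(X, y, spec, k=cv_folds, seed=seed, grid=grid)
    pipeline: Pipeline = search.best_estimator_
    X_model = _apply_preprocessing(pipeline, X)
    explanation = explain(pipeline.named_steps["model"], X_model, seed=seed)
    return explanation, pipeline


def _apply_preprocessing(pipeline: Pipeline, X) -> pd.DataFrame:
    for name, step in pipeline.steps[:-1]:
        X = step.transform(X)
    return X


def explanation_exports(explanation: ShapExplanation, out_dir, prefix: str = "shap"):
    """Write summary and per-sample attribution CSVs; returns the paths."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary_path = out_dir / f"{prefix}_summary.csv"
    sample_path = out_dir / f"{prefix}_per_sample.csv"
    explanation.summary_frame().to_csv(summary_path, index=False)
    explanation.per_sample_frame().to_csv(sample_path, index=False)
    return summary_path, sample_path


def plot_summary(explanation: ShapExplanation, out_path, top: int = 15):
    """Bar + violin relevance figure (top features by mean |φ|)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranked = rank_features(explanation)[:top]
    names = [n for n, _ in ranked][::-1]
    means = [v for _, v in ranked][::-1]
    idx = [explanation.feature_names.index(n) for n in names]
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 0.4 * top + 2), sharey=True)
    ax1.barh(names, means, color="#4477aa")
    ax1.set_xlabel("mean |SHAP| (mV)")
    ax2.violinplot([explanation.values[:, j] for j in idx],
                   positions=range(len(idx)), vert=False, showextrema=False)
    ax2.set_xlabel("SHAP value (mV)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
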