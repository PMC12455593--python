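"""Candidate regressors and model selection over an 80/20 split.

Candidates are sklearn-style estimators (fit/predict, ``get_params``) that
carry a ``name`` and accept encoded feature matrices from
:func:`visionair.schema.encode_features`: unscaled numerics plus integer
factor codes, with the categorical column list passed at construction so
tree learners can split on unordered level subsets.

The default roster is a gradient-boosted trees model (least-squares
stagewise boosting of depth-limited trees with native categorical splits
and learned missing-value routing), a bagged-trees forest, and a ridge
linear model on one-hot factors. Selection minimizes test-split RMSE, with
ties broken by lower unsystematic RMSE then name — test-set reliability
over raw train fit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder
from sklearn.utils.validation import check_is_fitted

from .metrics import FitReport, evaluate, rmse

__all__ = [
    "FunctionModel",
    "GradientBoostedTrees",
    "BaggedTrees",
    "RidgeOnFactors",
    "default_candidates",
    "split_cohort",
    "fit_candidates",
    "select_best",
]


class FunctionModel:
    """Wrap a plain function of a feature frame as a fitted predictor.

    Useful for closed-form oracles in tests and for probing the attribution
    and counterfactual machinery with known models.
    """

    def __init__(self, fn, name: str = "function"):
        self.fn = fn
        self.name = name

    def fit(self, X, y=None):
        return self

    def predict(self, X):
        return np.asarray(self.fn(X), dtype=float).ravel()


class GradientBoostedTrees(BaseEstimator, RegressorMixin):
    """Least-squares gradient-boosted regression trees.

    Stagewise boosting of depth-limited trees; categorical predictors split
    by level subsets on factor codes; missing values are routed to the child
    with lower training loss. ``learning_rate=0`` degenerates to the
    training-mean predictor. Deterministic given ``random_state`` and data.
    """

    name = "gbm"

    def __init__(
        self,
        n_trees: int = 300,
        depth: int = 6,
        learning_rate: float = 0.1,
        min_leaf: int = 20,
        categorical_features: list[str] | None = None,
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.depth = depth
        self.learning_rate = learning_rate
        self.min_leaf = min_leaf
        self.categorical_features = categorical_features
        self.random_state = random_state

    @property
    def hyperparams(self) -> dict:
        return self.get_params()

    def fit(self, X, y):
        if self.n_trees <= 0 or self.depth <= 0 or self.min_leaf <= 0 or self.learning_rate < 0:
            raise ValueError("hyperparameters must be positive (learning_rate >= 0)")
        y = np.asarray(y, dtype=float).ravel()
        if self.learning_rate == 0.0 or np.all(y == y[0]):
            # no boosting updates possible / constant target
            self.mean_ = float(np.mean(y))
            self.booster_ = None
            return self
        cats = None
        if self.categorical_features:
            cols = list(X.columns) if hasattr(X, "columns") else []
            cats = [c for c in self.categorical_features if not cols or c in cols]
        self.booster_ = HistGradientBoostingRegressor(
            loss="squared_error",
            max_iter=self.n_trees,
            max_depth=self.depth,
            learning_rate=self.learning_rate,
            min_samples_leaf=self.min_leaf,
            categorical_features=cats if cats else None,
            early_stopping=False,
            random_state=self.random_state,
        )
        self.booster_.fit(X, y)
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        check_is_fitted(self, "mean_")
        if self.booster_ is None:
            return np.full(len(X), self.mean_)
        return self.booster_.predict(X)

    def staged_train_rmse(self, X, y) -> np.ndarray:
        """Train RMSE after each boosting round (non-increasing)."""
        check_is_fitted(self, "mean_")
        y = np.asarray(y, dtype=float).ravel()
        if self.booster_ is None:
            return np.array([rmse(np.full_like(y, self.mean_), y)])
        return np.array([rmse(p, y) for p in self.booster_.staged_predict(X)])


class BaggedTrees(BaseEstimator, RegressorMixin):
    """Bagged regression trees (random-forest-style) candidate.

    Factor codes are consumed ordinally; adequate as a comparison candidate,
    not as the explained model of record.
    """

    name = "random_forest"

    def __init__(
        self,
        n_trees: int = 200,
        min_leaf: int = 5,
        categorical_features: list[str] | None = None,
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.min_leaf = min_leaf
        self.categorical_features = categorical_features
        self.random_state = random_state

    @property
    def hyperparams(self) -> dict:
        return self.get_params()

    def fit(self, X, y):
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_trees,
            min_samples_leaf=self.min_leaf,
            random_state=self.random_state,
            n_jobs=1,
        )
        self.forest_.fit(X, np.asarray(y, dtype=float).ravel())
        return self

    def predict(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict(X)


class RidgeOnFactors(BaseEstimator, RegressorMixin):
    """Ridge regression with one-hot expansion of the factor columns."""

    name = "ridge"

    def __init__(
        self,
        alpha: float = 1.0,
        categorical_features: list[str] | None = None,
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.categorical_features = categorical_features
        self.random_state = random_state

    @property
    def hyperparams(self) -> dict:
        return self.get_params()

    def fit(self, X, y):
        cats = [c for c in (self.categorical_features or []) if c in getattr(X, "columns", [])]
        ct = ColumnTransformer(
            [("onehot", OneHotEncoder(handle_unknown="ignore"), cats)],
            remainder="passthrough",
        )
        self.pipeline_ = Pipeline([("encode", ct), ("ridge", Ridge(alpha=self.alpha))])
        self.pipeline_.fit(X, np.asarray(y, dtype=float).ravel())
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(X)


def default_candidates(
    categorical_features: list[str] | None = None,
    random_state: int = 0,
    hyperparams: dict[str, dict] | None = None,
) -> list:
    """Default roster: gbm, random_forest, ridge (per-candidate overrides
    via ``hyperparams={'gbm': {...}, ...}``)."""
    hyperparams = hyperparams or {}
    roster = [
        GradientBoostedTrees(
            categorical_features=categorical_features,
            random_state=random_state,
            **hyperparams.get("gbm", {}),
        ),
        BaggedTrees(
            categorical_features=categorical_features,
            random_state=random_state,
            **hyperparams.get("random_forest", {}),
        ),
        RidgeOnFactors(
            categorical_features=categorical_features,
            random_state=random_state,
            **hyperparams.get("ridge", {}),
        ),
    ]
    return roster


def split_cohort(table: pd.DataFrame, fraction: float = 0.8, seed: int = 0):
    """Simple random 80/20 split: disjoint, exhaustive, unstratified, seeded.

    The test set gets floor(n * (1 - fraction)) rows.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(np.floor(n * (1.0 - fraction) + 1e-9))  # guard float roundoff
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return table.iloc[train_idx], table.iloc[test_idx]


def fit_candidates(X, y, candidates: list) -> list:
    """Fit every candidate on identical data; failures logged, not fatal."""
    if not candidates:
        raise ValueError("need at least one candidate")
    seen: dict[str, int] = {}
    fitted = []
    for cand in candidates:
        try:
            model = clone(cand)
        except TypeError:
            model = cand
        name = getattr(model, "name", type(model).__name__)
        if name in seen:
            seen[name] += 1
            new_name = f"{name}_{seen[name]}"
            warnings.warn(f"duplicate candidate name {name!r}; renamed to {new_name!r}", stacklevel=2)
            model.name = new_name
        else:
            seen[name] = 1
        try:
            model.fit(X, y)
        except Exception as exc:  # noqa: BLE001 - contract: log and exclude
            warnings.warn(f"candidate {name!r} failed to fit: {exc}", stacklevel=2)
            continue
        fitted.append(model)
    if not fitted:
        raise RuntimeError("all candidates failed to fit")
    return fitted


def select_best(reports: list[FitReport], split: str = "test") -> str:
    """Name of the model minimizing RMSE on the given split.

    Ties break by lower unsystematic RMSE (reliability), then name.
    """
    pool = [r for r in reports if r.split == split]
    if not pool:
        raise ValueError(f"no reports for split {split!r}")
    best = min(pool, key=lambda r: (r.rmse, r.rmse_u, r.model))
    return best.model
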