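"""Random-forest baselines operating on flattened descriptor windows.

The forests use 100 trees with maximum depth 10.  A 10 x 12 EDA-D window
flattens to 120 features, a 10 x 252 FAD window to 2520.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.utils.validation import check_is_fitted


def _flatten(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 3:
        return x.reshape(x.shape[0], -1)
    if x.ndim == 2:
        return x
    raise ValueError(f"expected (n, T, D) windows or (n, F) vectors, got {x.shape}")


class RandomForestWindowClassifier(ClassifierMixin, BaseEstimator):
    """RFc baseline: flatten windows, fit a 100-tree depth-10 forest."""

    def __init__(self, n_trees: int = 100, max_depth: int = 10,
                 random_state=None):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, x, y):
        xf = _flatten(x)
        y = np.asarray(y)
        if xf.shape[0] == 0:
            raise ValueError("empty training set")
        if np.unique(y).size < 2:
            raise ValueError("classification needs at least 2 classes present")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, max_depth=self.max_depth,
            random_state=self.random_state)
        self.forest_.fit(xf, y)
        self.classes_ = self.forest_.classes_
        return self

    def predict_proba(self, x):
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(_flatten(x))

    def predict(self, x):
        check_is_fitted(self, "forest_")
        return self.forest_.predict(_flatten(x))


class RandomForestWindowRegressor(RegressorMixin, BaseEstimator):
    """RFr baseline: flatten windows, fit a 100-tree depth-10 regressor."""

    def __init__(self, n_trees: int = 100, max_depth: int = 10,
                 random_state=None):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, x, y):
        xf = _flatten(x)
        if xf.shape[0] == 0:
            raise ValueError("empty training set")
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_trees, max_depth=self.max_depth,
            random_state=self.random_state)
        self.forest_.fit(xf, np.asarray(y, dtype=float))
        return self

    def predict(self, x):
        check_is_fitted(self, "forest_")
        return self.forest_.predict(_flatten(x))
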