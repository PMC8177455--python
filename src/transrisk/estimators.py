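"""scikit-learn estimator facade over the CHAID engine.

``ChaidClassifier`` exposes fit/predict/predict_proba and composes with
sklearn model selection; the fitted tree is available as ``tree_`` for
serialization, DOT export and test-fold reporting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .chaid import ChaidConfig, ChaidTree, PredictorSpec, binary_predictors, grow_tree


class ChaidClassifier(ClassifierMixin, BaseEstimator):
    """CHAID decision tree for a binary outcome over categorical predictors.

    Parameters mirror :class:`~transrisk.chaid.ChaidConfig`.  ``predictors``
    may be a list of :class:`PredictorSpec`; when None, every column of the
    training frame is treated as a free-nominal binary predictor.

    Attributes
    ----------
    tree_ : ChaidTree
        The fitted tree (node counts, merged groupings, adjusted p-values).
    classes_ : ndarray of shape (2,)
    """

    def __init__(
        self,
        alpha_split: float = 0.01,
        alpha_merge: float = 0.05,
        min_parent: int = 100,
        min_child: int = 50,
        max_depth: int = 3,
        bonferroni: bool = True,
        adjust_for_predictors: bool = True,
        predictors: list[PredictorSpec] | None = None,
    ):
        self.alpha_split = alpha_split
        self.alpha_merge = alpha_merge
        self.min_parent = min_parent
        self.min_child = min_child
        self.max_depth = max_depth
        self.bonferroni = bonferroni
        self.adjust_for_predictors = adjust_for_predictors
        self.predictors = predictors

    def _config(self) -> ChaidConfig:
        return ChaidConfig(
            alpha_split=self.alpha_split,
            alpha_merge=self.alpha_merge,
            min_parent=self.min_parent,
            min_child=self.min_child,
            max_depth=self.max_depth,
            bonferroni=self.bonferroni,
            adjust_for_predictors=self.adjust_for_predictors,
        )

    @staticmethod
    def _frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])

    def fit(self, X, y) -> "ChaidClassifier":
        frame = self._frame(X)
        y = np.asarray(y).astype(int)
        if len(frame) != len(y):
            raise ValueError("X and y lengths differ")
        classes = np.unique(y)
        if not np.isin(classes, [0, 1]).all():
            raise ValueError("outcome must be binary 0/1")
        specs = self.predictors
        if specs is None:
            specs = binary_predictors(list(frame.columns))
        self.tree_ = grow_tree(frame.reset_index(drop=True), y, specs, self._config())
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = frame.shape[1]
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "tree_")
        routed = self.tree_.predict(self._frame(X))
        p1 = routed["case_fraction"].to_numpy()
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def apply(self, X) -> np.ndarray:
        """Terminal node id for each record."""
        check_is_fitted(self, "tree_")
        return self.tree_.predict(self._frame(X))["node_id"].to_numpy()

    def get_tree(self) -> ChaidTree:
        check_is_fitted(self, "tree_")
        return self.tree_
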