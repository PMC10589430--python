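"""Bagged regression trees with explicit out-of-bag (OOB) bookkeeping.

This is a deliberately transparent random-forest regressor: bootstrap
samples are drawn here (not inside an opaque ensemble), so for every tree
the set of out-of-bag animals is known. That enables the OOB permutation
importance of Breiman's original formulation — for each feature, permute
its values among a tree's OOB samples and record the increase in OOB mean
squared error, averaged over trees — which is the feature-relevance
statistic the outcome-prediction analysis is built on.

Individual trees come from scikit-learn; the bagging, OOB tracking and
permutation importance are implemented here because the per-tree OOB
structure is the point.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted

__all__ = ["OOBRandomForestRegressor"]


def _resolve_max_features(max_features, n_features: int) -> int:
    """'third' -> ceil(p/3) (the standard regression-forest default)."""
    if max_features == "third":
        return int(np.ceil(n_features / 3))
    if isinstance(max_features, float):
        return max(1, int(round(max_features * n_features)))
    if max_features is None:
        return n_features
    return int(max_features)


class OOBRandomForestRegressor(BaseEstimator, RegressorMixin):
    """Bagged decision-tree regressor with out-of-bag permutation importance.

    Parameters
    ----------
    n_estimators : int
        Number of bootstrap trees.
    max_features : 'third', int, float or None
        Features considered per split; 'third' means ceil(p/3).
    min_samples_leaf, max_depth
        Passed to each tree.
    random_state : int or None
        Seeds both the bootstrap draws and the trees.

    Attributes
    ----------
    trees_ : list of DecisionTreeRegressor
    oob_indices_ : list of ndarray
        Row indices out-of-bag for each tree.
    oob_prediction_ : ndarray
        Per-sample mean prediction over the trees for which the sample was
        out-of-bag (NaN if a sample was in-bag everywhere).
    """

    def __init__(
        self,
        n_estimators: int = 500,
        max_features="third",
        min_samples_leaf: int = 2,
        max_depth: int | None = None,
        random_state: int | None = None,
        compute_oob: bool = True,
    ):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.max_depth = max_depth
        self.random_state = random_state
        self.compute_oob = compute_oob

    def fit(self, X, y) -> "OOBRandomForestRegressor":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2D")
        n, p = X.shape
        if y.shape != (n,):
            raise ValueError(f"y has shape {y.shape}, expected ({n},)")
        rng = np.random.default_rng(self.random_state)
        mf = _resolve_max_features(self.max_features, p)

        self.trees_ = []
        self.oob_indices_ = []
        oob_sum = np.zeros(n)
        oob_count = np.zeros(n)
        for _ in range(self.n_estimators):
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
            tree = DecisionTreeRegressor(
                max_features=mf,
                min_samples_leaf=self.min_samples_leaf,
                max_depth=self.max_depth,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[boot], y[boot])
            self.trees_.append(tree)
            self.oob_indices_.append(oob)
            if self.compute_oob and oob.size:
                oob_sum[oob] += tree.predict(X[oob])
                oob_count[oob] += 1

        if self.compute_oob:
            with np.errstate(invalid="ignore"):
                self.oob_prediction_ = np.where(
                    oob_count > 0, oob_sum / np.maximum(oob_count, 1), np.nan
                )
        else:
            self.oob_prediction_ = None
        self.n_features_in_ = p
        self._fit_X = X
        self._fit_y = y
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "trees_")
        X = np.asarray(X, dtype=np.float64)
        out = np.zeros(X.shape[0])
        for tree in self.trees_:
            out += tree.predict(X)
        return out / len(self.trees_)

    def oob_permutation_importance(self, random_state: int | None = None) -> np.ndarray:
        """Breiman-style OOB permutation importance per feature.

        For each tree and feature j: permute column j among the tree's OOB
        samples and measure the increase in OOB MSE over the unpermuted
        OOB MSE. Scores are averaged over trees. An uninformative feature
        scores ~0 (it can be slightly negative by chance); informative
        features score positive.
        """
        check_is_fitted(self, "trees_")
        rng = np.random.default_rng(random_state)
        X, y = self._fit_X, self._fit_y
        p = self.n_features_in_
        total = np.zeros(p)
        n_used = 0
        for tree, oob in zip(self.trees_, self.oob_indices_):
            m = oob.size
            if m < 2:
                continue
            Xo = X[oob]
            yo = y[oob]
            base = np.mean((tree.predict(Xo) - yo) ** 2)
            # one stacked predict call: p blocks of the OOB matrix, each with
            # a single column permuted
            stacked = np.tile(Xo, (p, 1))
            for j in range(p):
                perm = rng.permutation(m)
                stacked[j * m : (j + 1) * m, j] = Xo[perm, j]
            pred = tree.predict(stacked).reshape(p, m)
            mse = np.mean((pred - yo[None, :]) ** 2, axis=1)
            total += mse - base
            n_used += 1
        if n_used == 0:
            raise RuntimeError("no tree had >= 2 out-of-bag samples")
        return total / n_used
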