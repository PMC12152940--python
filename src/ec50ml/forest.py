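"""Random-forest regressors with quality-aware randomization.

All variants share one ensemble engine built on scikit-learn decision trees;
what differs is how the per-molecule quality metric z enters:

* ``RandomForest`` — uniform bootstrap + random feature selection (baseline;
  ignores z).
* ``ParametricBootstrapForest`` — each tree's bootstrap draws points with
  probability p_i ∝ exp(-α z_i) instead of uniformly.
* ``WeightedForest`` — uniform bootstrap, but splits maximize the *weighted*
  variance reduction with case weights n·p_i, and leaves hold weighted means.
* ``OutputSmearingForest`` — random feature selection is replaced by target
  smearing: each tree sees y_i + e_i with e_i ~ N(0, β), fresh per tree.
* ``VariableOutputSmearingForest`` — per-point smearing variance grows with z
  (worse-fitted molecules get more randomization); the mean variance across
  points is exactly β.

The engine is deliberately shared so that the α = 0 / β = 0 degeneracies are
structural: a parametric-bootstrap or weighted forest with α = 0 performs the
identical sequence of random draws and tree fits as the plain forest, and a
variable-output-smearing forest with α = 0 reduces to plain output smearing.

Determinism: every forest takes an integer ``seed``; per-tree RNG streams are
spawned from one ``numpy.random.SeedSequence``, so refitting with the same
data and seed reproduces predictions bit for bit.
"""

from __future__ import annotations

import numpy as np
from scipy.special import softmax
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted

from .weights import quality_weights

__all__ = [
    "RandomForest",
    "ParametricBootstrapForest",
    "WeightedForest",
    "OutputSmearingForest",
    "VariableOutputSmearingForest",
    "min_samples_split_count",
]


def min_samples_split_count(value: int | float, n_samples: int) -> int:
    """Convert a min_samples_split fraction to a count (round half up, floor 2).

    Fractions follow the convention that e.g. 2.5% of 500 training points is
    13.  Integer inputs pass through unchanged (floored at 2).
    """
    if isinstance(value, (int, np.integer)):
        return max(2, int(value))
    if not 0 < value <= 1:
        raise ValueError(f"fractional min_samples_split must be in (0, 1], got {value}")
    return max(2, int(np.floor(value * n_samples + 0.5)))


class _BaseForest(BaseEstimator, RegressorMixin):
    """Shared bootstrap-ensemble engine; subclasses customize how z is used."""

    def __init__(self, n_trees=250, max_features=1.0, min_samples_split=2, seed=0):
        self.n_trees = n_trees
        self.max_features = max_features
        self.min_samples_split = min_samples_split
        self.seed = seed

    # -- hooks -------------------------------------------------------------
    def _bootstrap_probs(self, z: np.ndarray | None, n: int) -> np.ndarray:
        return np.full(n, 1.0 / n)

    def _case_weights(self, z: np.ndarray | None, n: int) -> np.ndarray:
        return np.ones(n)

    def _smear_variances(self, z: np.ndarray | None, n: int) -> np.ndarray | None:
        return None

    def _tree_max_features(self):
        return self.max_features

    def _require_z(self, z, alpha):
        if not (np.isfinite(alpha) and alpha >= 0):
            raise ValueError("alpha must be nonnegative")
        if alpha > 0 and z is None:
            raise ValueError("quality metrics z are required when alpha > 0")

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y, z=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per target")
        n = len(y)
        if n == 0:
            raise ValueError("cannot fit a forest on an empty table")
        if z is not None:
            z = np.asarray(z, dtype=float)
            if len(z) != n:
                raise ValueError("z must have one entry per training row")
        self._validate_quality_params()
        probs = self._bootstrap_probs(z, n)
        weights = self._case_weights(z, n)
        smear_var = self._smear_variances(z, n)
        if smear_var is not None and not np.any(smear_var > 0):
            smear_var = None  # zero smearing degenerates to the plain bootstrap
        mss = min_samples_split_count(self.min_samples_split, n)

        trees = []
        root = np.random.SeedSequence(self.seed)
        for child in root.spawn(self.n_trees):
            rng = np.random.default_rng(child)
            idx = rng.choice(n, size=n, replace=True, p=probs)
            if smear_var is not None:
                yt = y + rng.standard_normal(n) * np.sqrt(smear_var)
            else:
                yt = y
            tree = DecisionTreeRegressor(
                max_features=self._tree_max_features(),
                min_samples_split=mss,
                random_state=int(rng.integers(2**31)),
            )
            tree.fit(X[idx], yt[idx], sample_weight=weights[idx])
            trees.append(tree)
        self.trees_ = trees
        self.n_features_in_ = X.shape[1]
        self.n_samples_ = n
        return self

    def _validate_quality_params(self) -> None:
        pass

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "trees_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature matrix has {X.shape[1] if X.ndim == 2 else 'wrong'} columns, "
                f"model was trained with {self.n_features_in_}"
            )
        pred = np.zeros(len(X))
        for tree in self.trees_:
            pred += tree.predict(X)
        return pred / len(self.trees_)

    def tree_predictions(self, X) -> np.ndarray:
        """(n_trees, n_rows) matrix of individual tree predictions."""
        check_is_fitted(self, "trees_")
        X = np.asarray(X, dtype=float)
        return np.vstack([t.predict(X) for t in self.trees_])


class RandomForest(_BaseForest):
    """Quality-blind baseline: uniform bootstrap + random feature selection."""


class ParametricBootstrapForest(_BaseForest):
    """Bootstrap draws follow p_i ∝ exp(-α z_i); α = 0 recovers RandomForest."""

    def __init__(self, alpha=1.0, n_trees=250, max_features=1.0, min_samples_split=2, seed=0):
        super().__init__(n_trees, max_features, min_samples_split, seed)
        self.alpha = alpha

    def _validate_quality_params(self):
        if not (np.isfinite(self.alpha) and self.alpha >= 0):
            raise ValueError("alpha must be nonnegative")

    def _bootstrap_probs(self, z, n):
        if z is None:
            if self.alpha > 0:
                raise ValueError("quality metrics z are required when alpha > 0")
            return np.full(n, 1.0 / n)
        return quality_weights(z, self.alpha).p


class WeightedForest(_BaseForest):
    """Splits maximize weighted variance reduction with case weights n·p_i."""

    def __init__(self, alpha=1.0, n_trees=250, max_features=1.0, min_samples_split=2, seed=0):
        super().__init__(n_trees, max_features, min_samples_split, seed)
        self.alpha = alpha

    def _validate_quality_params(self):
        if not (np.isfinite(self.alpha) and self.alpha >= 0):
            raise ValueError("alpha must be nonnegative")

    def _case_weights(self, z, n):
        if z is None:
            if self.alpha > 0:
                raise ValueError("quality metrics z are required when alpha > 0")
            return np.ones(n)
        return quality_weights(z, self.alpha).sample_weight


class OutputSmearingForest(_BaseForest):
    """Target smearing e_i ~ N(0, β) per tree replaces random feature selection."""

    def __init__(self, beta=1.0, n_trees=250, min_samples_split=2, seed=0):
        super().__init__(n_trees, 1.0, min_samples_split, seed)
        self.beta = beta

    def _validate_quality_params(self):
        if not (np.isfinite(self.beta) and self.beta >= 0):
            raise ValueError("beta (smearing variance) must be nonnegative")

    def _tree_max_features(self):
        return 1.0  # all features: smearing is the source of randomness

    def _smear_variances(self, z, n):
        return np.full(n, float(self.beta))


class VariableOutputSmearingForest(OutputSmearingForest):
    """Per-point smearing variance depends on the quality metric.

    Default mode ``"quality_scaled"`` sets variance_i = β·n·exp(+α z'_i) /
    Σ_j exp(+α z'_j) with z' the mean-scaled quality metric: worse-fitted
    points are smeared more, the mean variance across points is exactly β,
    and α = 0 degenerates to uniform smearing.  Mode ``"literal"`` instead
    uses variance_i = β·p_i with p_i ∝ exp(-α z_i), which assigns *more*
    smearing to the better-fitted points (kept for comparison only).
    """

    def __init__(
        self, alpha=1.0, beta=1.0, n_trees=250, min_samples_split=2, seed=0,
        smear_mode="quality_scaled",
    ):
        super().__init__(beta, n_trees, min_samples_split, seed)
        self.alpha = alpha
        self.smear_mode = smear_mode

    def _validate_quality_params(self):
        super()._validate_quality_params()
        if not (np.isfinite(self.alpha) and self.alpha >= 0):
            raise ValueError("alpha must be nonnegative")
        if self.smear_mode not in ("quality_scaled", "literal"):
            raise ValueError(f"unknown smear_mode {self.smear_mode!r}")

    def _smear_variances(self, z, n):
        if z is None:
            if self.alpha > 0:
                raise ValueError("quality metrics z are required when alpha > 0")
            return np.full(n, float(self.beta))
        if self.smear_mode == "literal":
            return float(self.beta) * quality_weights(z, self.alpha).p
        z = np.asarray(z, dtype=float)
        if np.any(z < 0) or not np.all(np.isfinite(z)):
            raise ValueError("quality metrics z must be finite and nonnegative")
        mean = z.mean()
        zs = z / mean if mean > 0 else z
        return float(self.beta) * n * softmax(self.alpha * zs)
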