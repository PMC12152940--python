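"""Support-vector regression, plain and quality-weighted.

Both use an RBF kernel with scikit-learn defaults except for the
epsilon-insensitive tube width, which is tuned.  The weighted variant scales
each training sample's loss penalty by the case weight n·p_i with
p_i ∝ exp(-α z_i), so poorly fitted molecules exert less pull on the fit;
α = 0 makes it identical to the plain SVR.  Neither model uses randomness,
so predictions are fully determined by the data and hyperparameters.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.svm import SVR as _SkSVR
from sklearn.utils.validation import check_is_fitted

from .weights import quality_weights

__all__ = ["SupportVectorRegressor", "WeightedSupportVectorRegressor"]


class SupportVectorRegressor(BaseEstimator, RegressorMixin):
    """RBF-kernel epsilon-SVR; ignores quality metrics."""

    def __init__(self, epsilon: float = 0.1):
        self.epsilon = epsilon

    def _check_epsilon(self):
        if not (np.isfinite(self.epsilon) and self.epsilon > 0):
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")

    def _sample_weight(self, z, n):
        return None

    def fit(self, X, y, z=None):
        self._check_epsilon()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self._svr = _SkSVR(kernel="rbf", epsilon=self.epsilon)
        self._svr.fit(X, y, sample_weight=self._sample_weight(z, len(y)))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "_svr")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature matrix has wrong width, model was trained with "
                f"{self.n_features_in_} features"
            )
        return self._svr.predict(X)


class WeightedSupportVectorRegressor(SupportVectorRegressor):
    """Epsilon-SVR with per-sample penalties n·p_i from the quality metrics."""

    def __init__(self, alpha: float = 1.0, epsilon: float = 0.1):
        super().__init__(epsilon=epsilon)
        self.alpha = alpha

    def _sample_weight(self, z, n):
        if not (np.isfinite(self.alpha) and self.alpha >= 0):
            raise ValueError("alpha must be nonnegative")
        if z is None:
            if self.alpha > 0:
                raise ValueError("quality metrics z are required when alpha > 0")
            return None
        return quality_weights(z, self.alpha).sample_weight
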