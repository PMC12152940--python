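"""Model specifications, training entry points and trained-model persistence.

A :class:`ModelSpec` names one of the seven model families and carries only
the hyperparameters that family actually tunes:

=========  =======================================  =========================
family     estimator                                 tunable hyperparameters
=========  =======================================  =========================
RF         RandomForest                              max_features, min_samples_split
PB_RF      ParametricBootstrapForest                 max_features, min_samples_split, alpha
W_RF       WeightedForest                            max_features, min_samples_split, alpha
OS_RF      OutputSmearingForest                      min_samples_split, beta
VOS_RF     VariableOutputSmearingForest              min_samples_split, beta, alpha
SVR        SupportVectorRegressor                    epsilon
WSVR       WeightedSupportVectorRegressor            epsilon, alpha
=========  =======================================  =========================

Every forest uses a fixed 250 trees by default so ensemble size never
confounds model comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import joblib
import numpy as np

from .data import QualityTargetTable
from .forest import (
    OutputSmearingForest,
    ParametricBootstrapForest,
    RandomForest,
    VariableOutputSmearingForest,
    WeightedForest,
)
from .svm import SupportVectorRegressor, WeightedSupportVectorRegressor

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "train_model",
    "fit_standard_rf",
    "fit_pb_rf",
    "fit_weighted_rf",
    "fit_os_rf",
    "fit_vos_rf",
    "fit_svr",
    "fit_wsvr",
    "FAMILY_HYPERPARAMS",
]

FAMILY_HYPERPARAMS: dict[str, frozenset[str]] = {
    "RF": frozenset({"max_features", "min_samples_split"}),
    "PB_RF": frozenset({"max_features", "min_samples_split", "alpha"}),
    "W_RF": frozenset({"max_features", "min_samples_split", "alpha"}),
    "OS_RF": frozenset({"min_samples_split", "beta"}),
    "VOS_RF": frozenset({"min_samples_split", "beta", "alpha"}),
    "SVR": frozenset({"epsilon"}),
    "WSVR": frozenset({"epsilon", "alpha"}),
}

_FOREST_FAMILIES = {"RF", "PB_RF", "W_RF", "OS_RF", "VOS_RF"}


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus its hyperparameters and ensemble settings."""

    family: str
    hyperparams: Mapping[str, float] = field(default_factory=dict)
    n_trees: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILY_HYPERPARAMS:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {sorted(FAMILY_HYPERPARAMS)}"
            )
        extra = set(self.hyperparams) - FAMILY_HYPERPARAMS[self.family]
        if extra:
            raise ValueError(
                f"hyperparameters {sorted(extra)} are not used by family {self.family}"
            )
        object.__setattr__(self, "hyperparams", dict(self.hyperparams))

    @property
    def uses_quality(self) -> bool:
        return "alpha" in FAMILY_HYPERPARAMS[self.family]

    def build(self):
        """Instantiate the (unfitted) estimator for this spec."""
        hp = dict(self.hyperparams)
        if self.family in _FOREST_FAMILIES:
            hp.setdefault("min_samples_split", 2)
            common = dict(
                n_trees=self.n_trees,
                min_samples_split=hp.pop("min_samples_split"),
                seed=self.seed,
            )
        if self.family == "RF":
            return RandomForest(max_features=hp.pop("max_features", 1.0), **common)
        if self.family == "PB_RF":
            return ParametricBootstrapForest(
                alpha=hp.pop("alpha", 0.0),
                max_features=hp.pop("max_features", 1.0),
                **common,
            )
        if self.family == "W_RF":
            return WeightedForest(
                alpha=hp.pop("alpha", 0.0),
                max_features=hp.pop("max_features", 1.0),
                **common,
            )
        if self.family == "OS_RF":
            return OutputSmearingForest(beta=hp.pop("beta", 1.0), **common)
        if self.family == "VOS_RF":
            return VariableOutputSmearingForest(
                alpha=hp.pop("alpha", 0.0), beta=hp.pop("beta", 1.0), **common
            )
        if self.family == "SVR":
            return SupportVectorRegressor(epsilon=hp.pop("epsilon", 0.1))
        return WeightedSupportVectorRegressor(
            alpha=hp.pop("alpha", 0.0), epsilon=hp.pop("epsilon", 0.1)
        )


@dataclass
class TrainedModel:
    """A fitted estimator together with its spec and training metadata."""

    spec: ModelSpec
    estimator: object
    n_training_molecules: int
    n_features: int

    def predict(self, features) -> np.ndarray:
        """Predicted LogEC50 per feature row (deterministic after fitting)."""
        features = np.asarray(features, dtype=float)
        if features.ndim != 2 or features.shape[1] != self.n_features:
            raise ValueError(
                f"expected a 2-D feature matrix with {self.n_features} columns"
            )
        pred = self.estimator.predict(features)
        if not np.all(np.isfinite(pred)):
            raise RuntimeError("model produced non-finite predictions")
        return pred

    def save(self, path) -> None:
        joblib.dump({"spec": self.spec, "model": self}, path)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        return joblib.load(path)["model"]


def train_model(table: QualityTargetTable, spec: ModelSpec) -> TrainedModel:
    """Fit the spec'd model on a quality-target table."""
    if len(table) == 0:
        raise ValueError("cannot train on an empty table")
    est = spec.build()
    est.fit(table.features, table.targets, z=table.quality)
    return TrainedModel(
        spec=spec,
        estimator=est,
        n_training_molecules=len(table),
        n_features=table.n_features,
    )


def _family_fitter(family: str):
    def fitter(table: QualityTargetTable, spec: ModelSpec) -> TrainedModel:
        if spec.family != family:
            raise ValueError(f"spec family {spec.family} does not match {family}")
        return train_model(table, spec)

    fitter.__name__ = f"fit_{family.lower()}"
    fitter.__doc__ = f"Fit a {family} model from a matching ModelSpec."
    return fitter


fit_standard_rf = _family_fitter("RF")
fit_pb_rf = _family_fitter("PB_RF")
fit_weighted_rf = _family_fitter("W_RF")
fit_os_rf = _family_fitter("OS_RF")
fit_vos_rf = _family_fitter("VOS_RF")
fit_svr = _family_fitter("SVR")
fit_wsvr = _family_fitter("WSVR")
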