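"""Hyperparameter search and molecule-level data splitting.

The search protocol is random-search cross-validation: 20 hyperparameter
combinations are sampled (without replacement, since the grids are small)
from the per-family grids below, each is scored by k-fold CV mean squared
error on the LogEC50 targets, and the argmin is refit on the full training
table.

Default grids::

    max_features       0.1, 0.33, 0.5, 1.0        (forests with feature selection)
    min_samples_split  1%, 2.5%, 5%, 10%          (all forests; fraction of training n)
    alpha              0, 0.33, 1, 2              (quality-aware families)
    beta               0.25, 1, 1.5, 2.5          (output-smearing families)
    epsilon            0.05, 0.1, 0.2, 0.5        (SVR families)

Splitting is always at the molecule level — every measurement of a molecule
lands on the same side — because the prediction task is per-molecule and
measurement-level splits would leak.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold

from .data import DoseResponseSet, QualityTargetTable
from .models import FAMILY_HYPERPARAMS, ModelSpec

__all__ = ["SearchSpace", "random_search", "split_dataset"]


@dataclass(frozen=True)
class SearchSpace:
    """Per-parameter candidate values plus search budget."""

    max_features: tuple[float, ...] = (0.1, 0.33, 0.5, 1.0)
    min_samples_split: tuple[float, ...] = (0.01, 0.025, 0.05, 0.10)
    alpha: tuple[float, ...] = (0.0, 0.33, 1.0, 2.0)
    beta: tuple[float, ...] = (0.25, 1.0, 1.5, 2.5)
    epsilon: tuple[float, ...] = (0.05, 0.1, 0.2, 0.5)
    n_iterations: int = 20
    cv_folds: int = 5

    def grid(self, family: str) -> list[dict[str, float]]:
        """Full factorial grid over the parameters the family tunes."""
        names = sorted(FAMILY_HYPERPARAMS[family])
        values = [getattr(self, name) for name in names]
        if any(len(v) == 0 for v in values):
            raise ValueError(f"empty candidate list in search space for {family}")
        return [dict(zip(names, combo)) for combo in itertools.product(*values)]


def random_search(
    table: QualityTargetTable,
    family: str,
    space: SearchSpace = SearchSpace(),
    seed: int = 0,
    n_trees: int = 250,
    model_seed: int = 0,
) -> ModelSpec:
    """Pick the hyperparameters with the smallest cross-validation MSE.

    Samples ``min(n_iterations, grid size)`` combinations uniformly without
    replacement; ties are broken in favour of the earliest-sampled
    combination.  Returns the winning (unfitted) :class:`ModelSpec`.
    """
    if len(table) < space.cv_folds:
        raise ValueError(
            f"table has {len(table)} rows but {space.cv_folds}-fold CV was requested"
        )
    grid = space.grid(family)
    rng = np.random.default_rng(seed)
    n_iter = min(space.n_iterations, len(grid))
    chosen = rng.choice(len(grid), size=n_iter, replace=False)
    candidates = [grid[i] for i in chosen]
    if len(candidates) == 1:
        return ModelSpec(family, candidates[0], n_trees=n_trees, seed=model_seed)

    X, y, z = table.features, table.targets, table.quality
    kf = KFold(n_splits=space.cv_folds, shuffle=True, random_state=int(rng.integers(2**31)))
    folds = list(kf.split(X))
    best_mse, best_hp = np.inf, None
    for hp in candidates:
        spec = ModelSpec(family, hp, n_trees=n_trees, seed=model_seed)
        sq_err_sum = 0.0
        for train_idx, val_idx in folds:
            est = spec.build()
            est.fit(X[train_idx], y[train_idx], z=z[train_idx])
            pred = est.predict(X[val_idx])
            sq_err_sum += float(np.sum((pred - y[val_idx]) ** 2))
        mse = sq_err_sum / len(y)
        if mse < best_mse:
            best_mse, best_hp = mse, hp
    return ModelSpec(family, best_hp, n_trees=n_trees, seed=model_seed)


def split_dataset(
    sets: Sequence[DoseResponseSet], train_fraction: float, seed: int = 0
) -> tuple[list[DoseResponseSet], list[DoseResponseSet]]:
    """Random molecule-level train/test split (75/25 for uniform-grid screens,
    50/50 for large heterogeneous collections).

    Deterministic for a fixed seed; the train size is round(fraction * n)
    clamped so both sides are non-empty.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    sets = sorted(sets, key=lambda s: s.molecule_id)
    n = len(sets)
    if n < 2:
        raise ValueError("need at least 2 molecules to split")
    order = np.random.default_rng(seed).permutation(n)
    n_train = min(n - 1, max(1, int(round(train_fraction * n))))
    train_idx = set(order[:n_train].tolist())
    train = [sets[i] for i in range(n) if i in train_idx]
    test = [sets[i] for i in range(n) if i not in train_idx]
    return train, test
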