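"""High-level pipeline steps: raw sets -> quality-target table -> trained model.

These functions tie the per-molecule analyses together so the CLI and the
evaluation protocol stay thin:

1. split molecules into train/test,
2. convert *training* dose-response sets into (LogEC50 target, quality z)
   via regression or Bayesian analysis,
3. train a (possibly quality-aware) model on targets + fingerprints,
4. score it by predicting the held-out raw measurements.

Test-set molecules never pass through curve fitting — their EC50s are never
computed.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bayes import NoiseModel, PriorConfig, BayesianHillModel, pooled_variance
from .data import DoseResponseSet, QualityTargetTable
from .hill import fit_hill_regression

__all__ = ["regression_targets", "bayesian_targets", "build_quality_table"]

logger = logging.getLogger("ec50ml")


def regression_targets(sets: Sequence[DoseResponseSet]) -> pd.DataFrame:
    """Nonlinear-regression analysis: LogEC50 + mean-squared-residual quality z."""
    rows = {}
    for drset in sets:
        res = fit_hill_regression(drset)
        rows[drset.molecule_id] = (res.log_ec50, res.quality)
    return _targets_frame(rows)


def bayesian_targets(
    sets: Sequence[DoseResponseSet],
    fallback_sigma2: float | None = None,
    prior: PriorConfig = PriorConfig(),
    n_draws: int = 1000,
    seed: int = 0,
    noise: NoiseModel | None = None,
) -> pd.DataFrame:
    """Posterior-grid analysis: posterior mean target + posterior variance quality.

    The noise variance is pooled across all replicated (molecule,
    concentration) groups of the supplied sets unless an explicit
    ``noise`` model is given.
    """
    if noise is None:
        noise = pooled_variance(sets, fallback_sigma2=fallback_sigma2)
        if noise.source.value == "fallback":
            logger.warning(
                "no replicated measurements: using fallback noise variance %.3g",
                noise.sigma2,
            )
    rng = np.random.default_rng(seed)
    rows = {}
    for drset in sorted(sets, key=lambda s: s.molecule_id):
        res = BayesianHillModel(drset, noise, prior).fit(n_draws=n_draws, rng=rng)
        rows[drset.molecule_id] = (res.target, res.quality)
    return _targets_frame(rows)


def _targets_frame(rows: dict[str, tuple[float, float]]) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["log_ec50", "quality"])
    df.index.name = "molecule_id"
    return df.sort_index()


def build_quality_table(
    targets: pd.DataFrame, features: Mapping[str, np.ndarray] | pd.DataFrame
) -> QualityTargetTable:
    """Join a targets frame (log_ec50, quality indexed by molecule_id) with features.

    The feature table may cover more molecules than the targets (e.g. the full
    assay when targets come from the training split); molecules with targets
    but no features are an error.
    """
    triples = [
        (str(mid), float(row["log_ec50"]), float(row["quality"]))
        for mid, row in targets.iterrows()
    ]
    wanted = {t[0] for t in triples}
    if isinstance(features, pd.DataFrame):
        features = features.loc[features.index.astype(str).isin(wanted)]
    else:
        features = {k: v for k, v in features.items() if k in wanted}
    return QualityTargetTable.from_fits(triples, features)
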