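"""Dose-response-level model evaluation and comparison statistics.

Models are scored not on how well they reproduce test-set EC50s — which may
themselves be unreliable — but on how well the EC50 they predict explains
the *raw* held-out measurements.  For every test measurement at log
concentration X the predicted response is the Hill curve evaluated at X with
LogEC50 equal to the model's prediction and the slope fixed at 1 (the
default slope; test molecules carry no slope information).  The score is the
RMSE over all held-out (dose, response) pairs, its uncertainty a bootstrap
SD over pairs, and paired models are compared with a one-sided Wilcoxon
signed-rank test on per-measurement squared errors at the 0.1% level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon as _scipy_wilcoxon

from .data import DoseResponseSet, clip_responses
from .hill import HillParameters, hill_response
from .models import TrainedModel

__all__ = [
    "EvaluationReport",
    "evaluate_on_dose_response",
    "bootstrap_rmse_sd",
    "WilcoxonComparison",
    "wilcoxon_compare",
]

SIGNIFICANCE_LEVEL = 0.001  # 0.1%: deliberately strict to limit type-I errors


@dataclass
class EvaluationReport:
    """Per-measurement predicted vs observed responses plus summary stats.

    ``pairs`` has one row per held-out measurement with columns
    molecule_id, log_concentration, observed (clipped), predicted.
    """

    pairs: pd.DataFrame
    model_label: str = ""
    split_meta: dict = field(default_factory=dict)

    REQUIRED = ("molecule_id", "log_concentration", "observed", "predicted")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.pairs.columns]
        if missing:
            raise ValueError(f"pairs frame missing columns {missing}")
        if len(self.pairs) == 0:
            raise ValueError("empty evaluation report")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def residuals(self) -> np.ndarray:
        return (self.pairs["observed"] - self.pairs["predicted"]).to_numpy()

    @property
    def squared_errors(self) -> np.ndarray:
        return self.residuals**2

    @property
    def rmse(self) -> float:
        """Root mean squared error over all held-out dose-response pairs."""
        return float(np.sqrt(self.squared_errors.mean()))

    def rmse_sd(self, n_boot: int = 1000, seed: int = 0) -> float:
        return bootstrap_rmse_sd(self, n_boot=n_boot, seed=seed)

    def summary(self, n_boot: int = 1000, seed: int = 0) -> str:
        return "\n".join(
            [
                f"Dose-response evaluation: {self.model_label or 'model'}",
                f"  measurements : {len(self)}",
                f"  molecules    : {self.pairs['molecule_id'].nunique()}",
                f"  RMSE         : {self.rmse:.2f}",
                f"  bootstrap SD : {self.rmse_sd(n_boot=n_boot, seed=seed):.2f}",
            ]
        )

    def to_csv(self, path) -> None:
        self.pairs.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, model_label: str = "") -> "EvaluationReport":
        pairs = pd.read_csv(path, dtype={"molecule_id": str})
        return cls(pairs=pairs, model_label=model_label)


def evaluate_on_dose_response(
    model: TrainedModel,
    test_sets: Sequence[DoseResponseSet],
    features: Mapping[str, np.ndarray] | pd.DataFrame,
    model_label: str = "",
    split_meta: dict | None = None,
) -> EvaluationReport:
    """Predict every held-out measurement from the model's EC50s.

    No curve is ever fitted to the test data: the model's predicted LogEC50
    plus a unit slope fully determine the predicted response at each tested
    concentration.  Observed responses are clipped into [0, 100] before the
    comparison, mirroring the treatment of training responses.
    """
    if isinstance(features, pd.DataFrame):
        lookup = {str(i): features.loc[i].to_numpy(dtype=float) for i in features.index}
    else:
        lookup = {k: np.asarray(v, dtype=float) for k, v in features.items()}
    missing = [s.molecule_id for s in test_sets if s.molecule_id not in lookup]
    if missing:
        raise KeyError(f"no features for test molecules: {sorted(missing)}")
    if not test_sets:
        raise ValueError("no test sets supplied")

    feat = np.vstack([lookup[s.molecule_id] for s in test_sets])
    pred_log_ec50 = model.predict(feat)

    rows = []
    for drset, log_ec50 in zip(test_sets, pred_log_ec50):
        ds = clip_responses(drset)
        params = HillParameters(float(log_ec50), 1.0, ds.direction)
        predicted = hill_response(params, ds.log_concentrations)
        rows.append(
            pd.DataFrame(
                {
                    "molecule_id": ds.molecule_id,
                    "log_concentration": ds.log_concentrations,
                    "observed": ds.responses,
                    "predicted": predicted,
                }
            )
        )
    return EvaluationReport(
        pairs=pd.concat(rows, ignore_index=True),
        model_label=model_label or model.spec.family,
        split_meta=split_meta or {},
    )


def bootstrap_rmse_sd(
    report: EvaluationReport, n_boot: int = 1000, seed: int = 0
) -> float:
    """SD of the RMSE under resampling of individual (observed, predicted) pairs."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    sq = report.squared_errors
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(sq), size=(n_boot, len(sq)))
    rmses = np.sqrt(sq[idx].mean(axis=1))
    return float(rmses.std())


@dataclass(frozen=True)
class WilcoxonComparison:
    """One-sided signed-rank comparison of two models' squared errors."""

    p_value: float
    direction: str  # "a_better" | "b_better" | "tied"
    significant: bool  # p < 0.001 in favour of a
    n_pairs: int  # pairs remaining after dropping zero differences
    method: str

    def __str__(self) -> str:
        verdict = "significantly better" if self.significant else "not significantly better"
        return (
            f"Wilcoxon signed-rank (one-sided, {self.n_pairs} informative pairs, "
            f"{self.method}): p = {self.p_value:.4g}; A is {verdict} than B "
            f"at the 0.1% level (trend: {self.direction})"
        )


def wilcoxon_compare(
    report_a: EvaluationReport, report_b: EvaluationReport
) -> WilcoxonComparison:
    """Test whether model A's per-measurement squared errors are smaller than B's.

    Both reports must cover the identical measurements in identical order.
    Zero differences are dropped; the exact null distribution is used for
    n <= 25 informative pairs (when ranks are untied), the normal
    approximation above that.  Identical reports return p = 1 by convention.
    """
    for col in ("molecule_id", "log_concentration", "observed"):
        a = report_a.pairs[col].to_numpy()
        b = report_b.pairs[col].to_numpy()
        if len(a) != len(b) or not (
            np.array_equal(a, b) if col == "molecule_id" else np.allclose(a, b)
        ):
            raise ValueError(
                "reports do not cover the identical test measurements in identical order"
            )
    d = report_a.squared_errors - report_b.squared_errors
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonComparison(1.0, "tied", False, 0, "degenerate")
    untied = len(np.unique(np.abs(d))) == n
    method = "exact" if (n <= 25 and untied) else "approx"
    res = _scipy_wilcoxon(d, alternative="less", method=method)
    # direction from the signed-rank statistic: W+ below its null mean favours a
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_plus = ranks[d > 0].sum()
    null_mean = n * (n + 1) / 4.0
    direction = "a_better" if w_plus < null_mean else ("b_better" if w_plus > null_mean else "tied")
    p = float(res.pvalue)
    return WilcoxonComparison(p, direction, p < SIGNIFICANCE_LEVEL, n, method)
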