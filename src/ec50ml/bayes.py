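"""Bayesian EC50 estimation on a discretized Hill-parameter posterior.

Measurement noise is modelled as i.i.d. Gaussian with a variance pooled
across all (molecule, concentration) groups that have replicate
measurements.  The posterior over (LogEC50, HillSlope) is evaluated on a
grid — by default 100 LogEC50 values uniform over the prior range (0.1x the
lowest to 10x the highest tested concentration, on the log10 scale) crossed
with 10 slope values uniform over [0.1, 10] — under uniform priors, then
normalized.  Drawing from the grid gives a posterior sample of LogEC50s
whose mean is the machine-learning target and whose variance is the quality
metric: a diffuse posterior (flat data, few points, heavy noise) yields a
large variance and flags an unreliable EC50.

All likelihood arithmetic is done in log space with max-subtraction, so
molecules with hundreds of measurements cannot underflow the grid to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np
from scipy.special import logsumexp

from .data import DoseResponseSet, clip_responses
from .hill import default_log_ec50_bounds

__all__ = [
    "NoiseSource",
    "NoiseModel",
    "pooled_variance",
    "PriorConfig",
    "PosteriorGrid",
    "posterior_grid",
    "BayesianHillModel",
    "BayesianHillResults",
    "posterior_summary",
]


class NoiseSource(str, Enum):
    POOLED = "pooled"
    FALLBACK = "fallback"


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement-noise variance (response units squared)."""

    sigma2: float
    source: NoiseSource = NoiseSource.POOLED

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma2) and self.sigma2 > 0):
            raise ValueError(f"sigma2 must be positive and finite, got {self.sigma2}")


def pooled_variance(
    sets: Iterable[DoseResponseSet], fallback_sigma2: float | None = None
) -> NoiseModel:
    """Pooled within-group variance over all replicated (molecule, concentration)
    groups.

    Groups with n_g >= 2 measurements contribute their unbiased variance s²_g
    with weight (n_g - 1):  sigma² = Σ (n_g-1) s²_g / Σ (n_g-1).  When no
    group has replicates (or the pooled estimate degenerates to zero), the
    configured ``fallback_sigma2`` — in practice the mean of pooled estimates
    from other assays — is used instead; if none is configured this raises.
    """
    ss = 0.0
    dof = 0
    for drset in sets:
        groups: dict[float, list[float]] = {}
        for m in drset.measurements:
            groups.setdefault(m.concentration, []).append(m.response)
        for values in groups.values():
            n = len(values)
            if n >= 2:
                ss += float(np.var(values, ddof=1)) * (n - 1)
                dof += n - 1
    if dof > 0 and ss > 0:
        return NoiseModel(ss / dof, NoiseSource.POOLED)
    if fallback_sigma2 is None:
        raise ValueError(
            "pooled variance is unavailable (no replicated groups, or zero "
            "within-group variance) and no fallback_sigma2 was configured"
        )
    return NoiseModel(fallback_sigma2, NoiseSource.FALLBACK)


@dataclass(frozen=True)
class PriorConfig:
    """Uniform prior grid configuration.

    ``log_ec50_range`` defaults to the data-driven range (0.1x min tested
    concentration .. 10x max, log10).  The slope prior spans [0.1, 10],
    covering every plausible Hill steepness.
    """

    n_log_ec50: int = 100
    n_slope: int = 10
    slope_range: tuple[float, float] = (0.1, 10.0)
    log_ec50_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_log_ec50 < 1 or self.n_slope < 1:
            raise ValueError("grid sizes must be >= 1")


@dataclass(frozen=True)
class PosteriorGrid:
    """Normalized posterior probabilities over the (LogEC50, slope) grid."""

    log_ec50_values: np.ndarray  # (n_log_ec50,)
    slope_values: np.ndarray  # (n_slope,)
    probabilities: np.ndarray  # (n_log_ec50, n_slope), sums to 1

    def __post_init__(self) -> None:
        if self.probabilities.shape != (len(self.log_ec50_values), len(self.slope_values)):
            raise ValueError("probability grid shape mismatch")
        if not np.isclose(self.probabilities.sum(), 1.0, atol=1e-9):
            raise ValueError("probabilities must sum to 1")

    @property
    def log_ec50_marginal(self) -> np.ndarray:
        return self.probabilities.sum(axis=1)

    def exact_moments(self) -> tuple[float, float]:
        """Exact posterior mean and variance of LogEC50 on the grid (no sampling)."""
        p = self.log_ec50_marginal
        mean = float(p @ self.log_ec50_values)
        var = float(p @ (self.log_ec50_values - mean) ** 2)
        return mean, var


def posterior_grid(
    drset: DoseResponseSet,
    noise: NoiseModel,
    prior: PriorConfig = PriorConfig(),
) -> PosteriorGrid:
    """Evaluate the discretized posterior for one molecule.

    For each grid pair the (unnormalized) log posterior is the Gaussian
    log-likelihood of the clipped responses under the Hill curve; uniform
    priors contribute only a constant and cancel in normalization.
    """
    ds = clip_responses(drset)
    x = ds.log_concentrations
    y = ds.responses
    lo, hi = (
        prior.log_ec50_range
        if prior.log_ec50_range is not None
        else default_log_ec50_bounds(ds.concentrations)
    )
    log_ec50s = np.linspace(lo, hi, prior.n_log_ec50)
    slopes = np.linspace(*prior.slope_range, prior.n_slope)

    # predicted responses, shape (n_log_ec50, n_slope, n_meas)
    exponent = (log_ec50s[:, None, None] - x[None, None, :]) * slopes[None, :, None]
    if ds.direction.value == "inhibition":
        exponent = -exponent
    with np.errstate(over="ignore"):
        pred = 100.0 / (1.0 + 10.0**exponent)
    loglik = -0.5 * np.sum((y[None, None, :] - pred) ** 2, axis=2) / noise.sigma2
    loglik -= logsumexp(loglik)  # normalize in log space (max-subtraction inside)
    return PosteriorGrid(log_ec50s, slopes, np.exp(loglik))


@dataclass(frozen=True)
class BayesianHillResults:
    """Posterior summary for one molecule: target = E[LogEC50], quality = Var[LogEC50]."""

    grid: PosteriorGrid
    target: float
    quality: float
    n_draws: int
    noise: NoiseModel

    def __post_init__(self) -> None:
        if self.quality < 0:
            raise ValueError("quality must be nonnegative")

    @property
    def log_ec50(self) -> float:
        return self.target

    def summary(self) -> str:
        return "\n".join(
            [
                "Bayesian Hill posterior summary",
                f"  LogEC50 (posterior mean): {self.target: .4f}",
                f"  quality (posterior var) : {self.quality: .6g}",
                f"  posterior draws         : {self.n_draws}",
                f"  noise sigma^2           : {self.noise.sigma2: .4g} ({self.noise.source.value})",
            ]
        )


def posterior_summary(
    grid: PosteriorGrid,
    n_draws: int = 1000,
    rng: np.random.Generator | int | None = 0,
    exact: bool = False,
) -> tuple[float, float]:
    """Mean/variance of a posterior LogEC50 sample drawn from the grid.

    ``exact=True`` bypasses sampling and returns the grid moments — useful in
    tests and when Monte-Carlo jitter is unwanted.  Deterministic for a fixed
    seed.
    """
    if exact:
        return grid.exact_moments()
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    p = grid.log_ec50_marginal
    draws = gen.choice(grid.log_ec50_values, size=n_draws, replace=True, p=p / p.sum())
    return float(draws.mean()), float(draws.var())


class BayesianHillModel:
    """Posterior-grid Hill model for one molecule (statsmodels-style wrapper)."""

    def __init__(
        self,
        data: DoseResponseSet,
        noise: NoiseModel,
        prior: PriorConfig = PriorConfig(),
    ) -> None:
        self.data = data
        self.noise = noise
        self.prior = prior

    def fit(
        self,
        n_draws: int = 1000,
        rng: np.random.Generator | int | None = 0,
        exact: bool = False,
    ) -> BayesianHillResults:
        grid = posterior_grid(self.data, self.noise, self.prior)
        target, quality = posterior_summary(grid, n_draws=n_draws, rng=rng, exact=exact)
        return BayesianHillResults(
            grid=grid, target=target, quality=quality, n_draws=0 if exact else n_draws,
            noise=self.noise,
        )
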