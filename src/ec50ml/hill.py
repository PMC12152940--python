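"""Two-parameter Hill model: evaluation and nonlinear least-squares fitting.

The response curve is

    response(X) = 100 / (1 + 10^((LogEC50 - X) * HillSlope))        (efficacy)

with ``X = log10(concentration)``.  The asymptotes are fixed at 0 and 100, so
the model has two free parameters: the midpoint ``LogEC50`` (the log10
concentration giving a 50% response) and the steepness ``HillSlope``.
Inhibition assays use the mirrored, strictly decreasing curve with the same
midpoint semantics (50% inhibition at the IC50).

Fitting follows the classic nonlinear-regression recipe: clip responses into
[0, 100], minimise the squared error with :func:`scipy.optimize.curve_fit`,
and fix the slope at 1 when the design cannot support a slope estimate (fewer
than three distinct concentrations).  The mean squared residual per molecule
is kept as a fit-quality metric z — small z means the curve pins down the
EC50 well, large z flags an unreliable value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .data import Direction, DoseResponseSet, clip_responses

__all__ = [
    "HillParameters",
    "hill_response",
    "HillCurveModel",
    "HillCurveResults",
    "HillFitError",
    "fit_hill_regression",
    "default_log_ec50_bounds",
]

SLOPE_BOUNDS = (0.1, 10.0)


@dataclass(frozen=True)
class HillParameters:
    """Fitted midpoint and steepness of a Hill curve."""

    log_ec50: float
    hill_slope: float
    direction: Direction = Direction.EFFICACY

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction(self.direction))
        if not np.isfinite(self.log_ec50):
            raise ValueError("log_ec50 must be finite")
        if not (np.isfinite(self.hill_slope) and self.hill_slope > 0):
            raise ValueError("hill_slope must be positive and finite")


def hill_response(params: HillParameters, log_concentration) -> np.ndarray | float:
    """Evaluate the Hill curve at ``X = log_concentration`` (log10 units).

    Returns values in (0, 100); exactly 50 at X = LogEC50 for every slope.
    Efficacy curves increase with X, inhibition curves decrease.
    """
    x = np.asarray(log_concentration, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("log_concentration must be finite")
    exponent = (params.log_ec50 - x) * params.hill_slope
    if params.direction is Direction.INHIBITION:
        exponent = -exponent
    # 10**exponent overflows harmlessly to inf for extreme X -> response 0
    with np.errstate(over="ignore"):
        out = 100.0 / (1.0 + 10.0**exponent)
    return out if out.ndim else float(out)


def default_log_ec50_bounds(concentrations: np.ndarray) -> tuple[float, float]:
    """LogEC50 search/prior range: 0.1x the lowest to 10x the highest tested
    concentration, in log10 units."""
    c = np.asarray(concentrations, dtype=float)
    return float(np.log10(0.1 * c.min())), float(np.log10(10.0 * c.max()))


class HillFitError(RuntimeError):
    """Nonlinear regression failed for a molecule (carries the molecule_id)."""

    def __init__(self, molecule_id: str, message: str) -> None:
        super().__init__(f"Hill fit failed for molecule {molecule_id!r}: {message}")
        self.molecule_id = molecule_id


@dataclass(frozen=True)
class HillCurveResults:
    """Results of a Hill-curve fit for one molecule.

    Attributes
    ----------
    params : HillParameters
        Fitted LogEC50 and HillSlope.
    quality : float
        z — the mean squared residual of the fitted curve (sum of squared
        residuals divided by the number of measurements).  Used downstream as
        the reliability score of the EC50.
    slope_fixed : bool
        True when the slope was pinned at 1 because fewer than three distinct
        concentrations were available.
    """

    model: "HillCurveModel"
    params: HillParameters
    quality: float
    slope_fixed: bool
    n_measurements: int

    def __post_init__(self) -> None:
        if self.quality < 0:
            raise ValueError("quality must be nonnegative")
        if self.slope_fixed and self.params.hill_slope != 1.0:
            raise ValueError("slope_fixed implies hill_slope == 1")

    @property
    def log_ec50(self) -> float:
        return self.params.log_ec50

    @property
    def hill_slope(self) -> float:
        return self.params.hill_slope

    # QualityTargetTable.from_fits looks for .target/.quality
    @property
    def target(self) -> float:
        return self.params.log_ec50

    def predict(self, log_concentration) -> np.ndarray | float:
        return hill_response(self.params, log_concentration)

    def residuals(self) -> np.ndarray:
        ds = self.model.clipped
        return ds.responses - hill_response(self.params, ds.log_concentrations)

    def summary(self) -> str:
        p = self.params
        lines = [
            f"Hill curve fit: molecule {self.model.data.molecule_id}",
            f"  direction     : {p.direction.value}",
            f"  LogEC50       : {p.log_ec50: .4f}",
            f"  HillSlope     : {p.hill_slope: .4f}" + ("  (fixed)" if self.slope_fixed else ""),
            f"  quality z     : {self.quality: .6g}",
            f"  n measurements: {self.n_measurements}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the clipped data and the fitted curve (returns the axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ds = self.model.clipped
        x = ds.log_concentrations
        grid = np.linspace(x.min() - 1, x.max() + 1, 200)
        ax.scatter(x, ds.responses, color="k", zorder=3, label="measurements")
        ax.plot(grid, hill_response(self.params, grid), label="fit")
        ax.axvline(self.params.log_ec50, ls=":", color="grey")
        ax.set_xlabel("log10 concentration")
        ax.set_ylabel("response (%)")
        ax.set_title(f"{self.model.data.molecule_id}: z = {self.quality:.3g}")
        ax.legend()
        return ax


class HillCurveModel:
    """Nonlinear least-squares Hill model for one molecule's dose-response set.

    Parameters
    ----------
    data : DoseResponseSet
        Raw measurements; responses are clipped into [0, 100] before fitting.
    log_ec50_bounds : optional (lo, hi)
        Search bounds for LogEC50; defaults to 0.1x min .. 10x max tested
        concentration.
    """

    def __init__(
        self,
        data: DoseResponseSet,
        log_ec50_bounds: tuple[float, float] | None = None,
    ) -> None:
        self.data = data
        self.clipped = clip_responses(data)
        self.log_ec50_bounds = (
            log_ec50_bounds
            if log_ec50_bounds is not None
            else default_log_ec50_bounds(data.concentrations)
        )

    def fit(self) -> HillCurveResults:
        ds = self.clipped
        x = ds.log_concentrations
        y = ds.responses
        lo, hi = self.log_ec50_bounds
        direction = ds.direction
        slope_fixed = ds.n_distinct_concentrations < 3

        def curve_2p(xv, log_ec50, slope):
            return hill_response(HillParameters(log_ec50, slope, direction), xv)

        def curve_1p(xv, log_ec50):
            return hill_response(HillParameters(log_ec50, 1.0, direction), xv)

        x0 = 0.5 * (lo + hi)
        starts = [x0] + list(np.linspace(lo, hi, 5))
        best: tuple[float, np.ndarray] | None = None
        last_err = "no start converged"
        for start in starts:
            try:
                if slope_fixed:
                    popt, _ = curve_fit(
                        curve_1p, x, y, p0=[start], bounds=([lo], [hi]), maxfev=2000
                    )
                    popt = np.array([popt[0], 1.0])
                else:
                    popt, _ = curve_fit(
                        curve_2p,
                        x,
                        y,
                        p0=[start, 1.0],
                        bounds=([lo, SLOPE_BOUNDS[0]], [hi, SLOPE_BOUNDS[1]]),
                        maxfev=2000,
                    )
            except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
                last_err = str(exc)
                continue
            params = HillParameters(popt[0], popt[1], direction)
            sse = float(np.sum((y - hill_response(params, x)) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt)
            if start == x0 and sse <= 1e-12 * len(y):
                break  # initial fit already exact; skip grid restarts
        # last-resort coarse grid search: cannot fail, and for flat or wildly
        # noisy sets it often beats a stalled local optimizer
        grid_ec50 = np.linspace(lo, hi, 200)
        grid_slope = np.array([1.0]) if slope_fixed else np.geomspace(*SLOPE_BOUNDS, 12)
        exponent = (grid_ec50[:, None, None] - x[None, None, :]) * grid_slope[None, :, None]
        if direction.value == "inhibition":
            exponent = -exponent
        with np.errstate(over="ignore"):
            pred = 100.0 / (1.0 + 10.0**exponent)
        sse_grid = np.sum((y[None, None, :] - pred) ** 2, axis=2)
        i, j = np.unravel_index(np.argmin(sse_grid), sse_grid.shape)
        if best is None or sse_grid[i, j] < best[0]:
            best = (float(sse_grid[i, j]), np.array([grid_ec50[i], grid_slope[j]]))
        sse, popt = best
        params = HillParameters(popt[0], popt[1], direction)
        return HillCurveResults(
            model=self,
            params=params,
            quality=sse / len(y),
            slope_fixed=slope_fixed,
            n_measurements=len(y),
        )


def fit_hill_regression(drset: DoseResponseSet, **kwargs) -> HillCurveResults:
    """Convenience wrapper: ``HillCurveModel(drset, **kwargs).fit()``."""
    return HillCurveModel(drset, **kwargs).fit()
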