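"""Quality metric -> bootstrap/weighting probabilities.

The transform p_i ∝ exp(-α z_i) turns per-molecule fit-quality metrics into a
probability distribution over training points: α = 0 ignores quality (uniform
p) and larger α concentrates mass on the well-fitted (low z) molecules.

By default z is divided by its training-set mean before exponentiation, so a
single α grid is comparable across datasets whose raw quality metrics differ
by orders of magnitude; ``scaling="raw"`` disables this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax

__all__ = ["WeightVector", "quality_weights"]


@dataclass(frozen=True)
class WeightVector:
    """Selection probabilities p (sum to 1) derived from quality metrics."""

    p: np.ndarray
    alpha: float
    z_scaling: str = "mean_scaled"

    def __post_init__(self) -> None:
        if not np.isclose(self.p.sum(), 1.0):
            raise ValueError("probabilities must sum to 1")

    def __len__(self) -> int:
        return len(self.p)

    @property
    def sample_weight(self) -> np.ndarray:
        """Per-sample case weights n * p_i (mean 1); uniform p gives all-ones."""
        return len(self.p) * self.p


def quality_weights(
    z, alpha: float, scaling: str = "mean_scaled"
) -> WeightVector:
    """Compute p_i ∝ exp(-α z'_i) with z' = z / mean(z) (or raw z).

    Larger z (worse fit) always gets a smaller probability; α = 0 returns the
    uniform distribution regardless of z.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or len(z) == 0:
        raise ValueError("z must be a non-empty 1-D array")
    if not np.all(np.isfinite(z)) or np.any(z < 0):
        raise ValueError("quality metrics z must be finite and nonnegative")
    if not (np.isfinite(alpha) and alpha >= 0):
        raise ValueError("alpha must be nonnegative")
    if scaling == "mean_scaled":
        mean = z.mean()
        zs = z / mean if mean > 0 else z
    elif scaling == "raw":
        zs = z
    else:
        raise ValueError(f"unknown z scaling {scaling!r}")
    p = softmax(-alpha * zs)
    return WeightVector(p=p, alpha=float(alpha), z_scaling=scaling)
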