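"""Core containers for dose-response data.

A dose-response experiment measures the percent effect of a molecule at a
series of concentrations.  Everything downstream (curve fitting, posterior
analysis, model training) consumes :class:`DoseResponseSet` objects — one per
molecule — and the per-molecule training payload is assembled into a
:class:`QualityTargetTable`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Direction",
    "Measurement",
    "DoseResponseSet",
    "QualityTargetTable",
    "clip_responses",
    "AlignmentError",
]


class Direction(str, Enum):
    """Assay direction: response rises (efficacy/EC50) or falls (inhibition/IC50)
    with concentration."""

    EFFICACY = "efficacy"
    INHIBITION = "inhibition"


@dataclass(frozen=True)
class Measurement:
    """A single (concentration, response) observation.

    ``response`` is a percent effect, nominally in [0, 100] but stored exactly
    as recorded — instruments routinely report values slightly outside the
    range and clipping is an explicit downstream step.
    """

    concentration: float
    response: float
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.concentration) or self.concentration <= 0:
            raise ValueError(
                f"concentration must be a positive finite number, got {self.concentration!r}"
            )
        if not math.isfinite(self.response):
            raise ValueError(f"response must be finite, got {self.response!r}")

    @property
    def log_concentration(self) -> float:
        """log10 of the concentration — the x-axis of every dose-response curve."""
        return math.log10(self.concentration)


@dataclass(frozen=True)
class DoseResponseSet:
    """All measurements recorded for one molecule in one assay."""

    molecule_id: str
    measurements: tuple[Measurement, ...]
    direction: Direction = Direction.EFFICACY

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurements", tuple(self.measurements))
        object.__setattr__(self, "direction", Direction(self.direction))
        if len(self.measurements) == 0:
            raise ValueError(
                f"molecule {self.molecule_id!r} has no measurements; "
                "molecules without recorded measurements must be removed upstream"
            )

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([m.concentration for m in self.measurements])

    @property
    def log_concentrations(self) -> np.ndarray:
        return np.log10(self.concentrations)

    @property
    def responses(self) -> np.ndarray:
        return np.array([m.response for m in self.measurements])

    @property
    def n_distinct_concentrations(self) -> int:
        return len({m.concentration for m in self.measurements})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "molecule_id": self.molecule_id,
                "concentration": self.concentrations,
                "response": self.responses,
            }
        )


def clip_responses(drset: DoseResponseSet) -> DoseResponseSet:
    """Clip responses into [0, 100].

    Values below 0 become 0 and values above 100 become 100, so every response
    is representable by a Hill curve with asymptotes at 0 and 100.  Order and
    count are preserved; the operation is idempotent.
    """
    clipped = tuple(
        Measurement(m.concentration, min(100.0, max(0.0, m.response)), m.replicate_id)
        for m in drset.measurements
    )
    return DoseResponseSet(drset.molecule_id, clipped, drset.direction)


class AlignmentError(ValueError):
    """Raised when per-molecule inputs cannot be aligned by molecule_id."""


class QualityTargetTable:
    """Per-molecule training payload: features, LogEC50 target and quality metric z.

    Rows are sorted by ``molecule_id`` so the table is deterministic regardless
    of input order.  ``quality`` is the fit-quality metric (mean squared curve
    residual, or posterior variance in Bayesian mode); larger means a less
    reliable target.
    """

    def __init__(
        self,
        molecule_ids: Sequence[str],
        features: np.ndarray,
        targets: Sequence[float],
        quality: Sequence[float],
    ) -> None:
        ids = np.asarray(molecule_ids, dtype=object)
        features = np.asarray(features, dtype=float)
        targets = np.asarray(targets, dtype=float)
        quality = np.asarray(quality, dtype=float)
        if features.ndim == 1:
            features = features.reshape(len(ids), -1) if len(ids) else features.reshape(0, 0)
        if not (len(ids) == len(features) == len(targets) == len(quality)):
            raise AlignmentError(
                "molecule_ids, features, targets and quality must have equal length"
            )
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate molecule_ids in table")
        if np.any(quality < 0):
            raise ValueError("quality metrics must be nonnegative")
        order = np.argsort(ids)
        self.molecule_ids: np.ndarray = ids[order]
        self.features: np.ndarray = features[order] if len(ids) else features
        self.targets: np.ndarray = targets[order]
        self.quality: np.ndarray = quality[order]

    def __len__(self) -> int:
        return len(self.molecule_ids)

    @property
    def n_features(self) -> int:
        return self.features.shape[1] if self.features.ndim == 2 else 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=[f"f{i}" for i in range(self.n_features)])
        df.insert(0, "molecule_id", self.molecule_ids)
        df["log_ec50"] = self.targets
        df["quality"] = self.quality
        return df

    @classmethod
    def from_fits(
        cls,
        fits: Mapping[str, "object"] | Iterable[tuple[str, float, float]],
        features: Mapping[str, np.ndarray] | pd.DataFrame,
    ) -> "QualityTargetTable":
        """Assemble a table from per-molecule fit results and a feature lookup.

        ``fits`` maps molecule_id to any object with ``target`` and ``quality``
        attributes (HillCurveResults and BayesianHillResults both qualify), or is
        an iterable of (molecule_id, target, quality) triples.  ``features`` maps
        molecule_id to a feature vector (dict or DataFrame indexed by id).
        Molecule sets must match exactly; mismatches raise AlignmentError naming
        the offenders.
        """
        if isinstance(fits, Mapping):
            triples = [(mid, f.target, f.quality) for mid, f in fits.items()]
        else:
            triples = [tuple(t) for t in fits]
        fit_ids = {t[0] for t in triples}
        if isinstance(features, pd.DataFrame):
            feat_ids = set(features.index.astype(str))
            getter = lambda mid: features.loc[mid].to_numpy(dtype=float)
        else:
            feat_ids = set(features)
            getter = lambda mid: np.asarray(features[mid], dtype=float)
        missing_feats = sorted(fit_ids - feat_ids)
        missing_fits = sorted(feat_ids - fit_ids)
        if missing_feats or missing_fits:
            raise AlignmentError(
                f"molecule sets differ: fits without features {missing_feats}, "
                f"features without fits {missing_fits}"
            )
        if not triples:
            return cls([], np.empty((0, 0)), [], [])
        ids = [t[0] for t in triples]
        feats = np.vstack([getter(mid) for mid in ids])
        return cls(ids, feats, [t[1] for t in triples], [t[2] for t in triples])
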