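"""Readers and writers for the package's plain-text formats.

Dose-response data travel as long-format CSV with columns
``molecule_id, concentration, response`` (one measurement per row, one
concentration unit per file).  Features travel as a wide CSV with a
``molecule_id`` column followed by 0/1 feature columns, or are computed on
the fly from SMILES via 1024-bit Morgan fingerprints.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import Direction, DoseResponseSet, Measurement

__all__ = [
    "read_dose_response_csv",
    "write_dose_response_csv",
    "read_features_csv",
    "write_features_csv",
    "featurize_smiles",
]

logger = logging.getLogger("ec50ml")


class CSVFormatError(ValueError):
    """Malformed input CSV; message carries 1-based data line numbers."""


def read_dose_response_csv(
    path, direction: Direction | str = Direction.EFFICACY
) -> list[DoseResponseSet]:
    """Load one DoseResponseSet per molecule from a long-format CSV.

    Rows with non-numeric fields or nonpositive concentrations raise
    :class:`CSVFormatError` citing the offending line.  Molecules appearing
    in the header-only sense (no rows) simply never materialize; sets are
    returned sorted by molecule_id.
    """
    direction = Direction(direction)
    path = Path(path)
    df = pd.read_csv(path, dtype={"molecule_id": str})
    required = {"molecule_id", "concentration", "response"}
    if not required.issubset(df.columns):
        raise CSVFormatError(
            f"{path}: header must contain {sorted(required)}, got {list(df.columns)}"
        )
    bad_lines = []
    for col in ("concentration", "response"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | ~np.isfinite(values)
        if col == "concentration":
            bad |= values <= 0
        bad_lines.extend((df.index[bad] + 2).tolist())  # +2: header + 1-based
        df[col] = values
    if bad_lines:
        raise CSVFormatError(
            f"{path}: invalid concentration/response on line(s) {sorted(set(bad_lines))} "
            "(values must be numeric and concentrations positive)"
        )
    sets = []
    for mid, group in df.groupby("molecule_id", sort=True):
        measurements = tuple(
            Measurement(float(c), float(r))
            for c, r in zip(group["concentration"], group["response"])
        )
        sets.append(DoseResponseSet(str(mid), measurements, direction))
    return sets


def write_dose_response_csv(sets: Sequence[DoseResponseSet], path) -> None:
    frames = [s.to_frame() for s in sorted(sets, key=lambda s: s.molecule_id)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_features_csv(path) -> pd.DataFrame:
    """Feature matrix keyed by molecule_id (first column)."""
    df = pd.read_csv(path, dtype={"molecule_id": str})
    if "molecule_id" not in df.columns:
        raise CSVFormatError(f"{path}: feature CSV must have a molecule_id column")
    df = df.set_index("molecule_id")
    return df.astype(float)


def write_features_csv(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=True, index_label="molecule_id")


def featurize_smiles(
    smiles: Sequence[str], n_bits: int = 1024, radius: int = 2
) -> np.ndarray:
    """Morgan (circular) fingerprints as 0/1 rows of length ``n_bits``.

    Unparseable SMILES are collected and reported in one error rather than
    silently dropped.  Requires RDKit (the ``chem`` extra).
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows = []
    bad = []
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            bad.append(s)
            continue
        rows.append(np.array(gen.GetFingerprint(mol), dtype=np.int8))
    if bad:
        raise ValueError(f"unparseable SMILES: {bad}")
    if not rows:
        return np.empty((0, n_bits), dtype=np.int8)
    return np.vstack(rows)
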