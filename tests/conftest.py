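import numpy as np
import pytest

from ec50ml.data import DoseResponseSet, Measurement, QualityTargetTable
from ec50ml.hill import HillParameters, hill_response


def make_set(molecule_id, log_ec50, slope=1.0, x=None, sigma=0.0, seed=0,
             direction="efficacy"):
    """Dose-response set from a known Hill curve plus optional Gaussian noise."""
    if x is None:
        x = np.linspace(-2.5, 1.0, 8)
    x = np.asarray(x, dtype=float)
    params = HillParameters(log_ec50, slope, direction)
    clean = np.asarray(hill_response(params, x), dtype=float).reshape(-1)
    rng = np.random.default_rng(seed)
    resp = clean + (rng.normal(0.0, sigma, len(x)) if sigma > 0 else 0.0)
    return DoseResponseSet(
        molecule_id,
        tuple(Measurement(10.0**xx, float(r)) for xx, r in zip(x, resp)),
        direction,
    )


@pytest.fixture
def toy_table():
    """Small deterministic training table: 40 molecules, 8 binary features."""
    rng = np.random.default_rng(42)
    X = (rng.random((40, 8)) < 0.4).astype(float)
    y = X[:, 0] * 2.0 - X[:, 1] + 0.1 * rng.standard_normal(40)
    z = rng.random(40)
    ids = [f"m{i:02d}" for i in range(40)]
    return QualityTargetTable(ids, X, y, z)
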