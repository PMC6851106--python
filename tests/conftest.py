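import numpy as np
import pytest

from gastrosyn.median_effect import MedianEffectModel
from gastrosyn.study import DoseResponseStudy


def exact_study(dm: float, m: float, doses, control_mean: float = 100.0, n: int = 3,
                treatment_id: str = "drug") -> DoseResponseStudy:
    """Noiseless study whose group means sit exactly on the median-effect curve."""
    doses = np.asarray(doses, dtype=float)
    fa = (doses / dm) ** m / (1.0 + (doses / dm) ** m)
    all_doses = [0.0] * n
    areas = [control_mean] * n
    ids = [f"C{i}" for i in range(n)]
    for j, (d, f) in enumerate(zip(doses, fa)):
        all_doses += [float(d)] * n
        areas += [control_mean * (1.0 - f)] * n
        ids += [f"D{j}-{i}" for i in range(n)]
    return DoseResponseStudy(treatment_id, ids, np.array(all_doses), np.array(areas))


@pytest.fixture
def unit_fit() -> MedianEffectModel:
    """Hyperbolic reference curve: Dm = 1, m = 1."""
    return MedianEffectModel.from_params(1.0, 1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
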