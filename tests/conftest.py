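import numpy as np
import pandas as pd
import pytest

from tmrqc.indexes import TRAIT_NAMES, AlleyBatch
from tmrqc.synthetic import GeneratorConfig


@pytest.fixture
def small_config():
    """Small but statistically faithful generator configuration."""
    return GeneratorConfig(seed=7, n_samples=60)


@pytest.fixture
def uniform_batch():
    """Alley batch with 16 literally identical points for every trait."""
    values = {"S4": 34.2, "S5": 17.9, "bottom": 17.8, "GMPL": 6.4,
              "CP": 15.2, "aNDF": 33.1, "starch": 26.0}
    fresh = pd.DataFrame({t: np.full(16, v) for t, v in values.items()})
    return AlleyBatch(fresh=fresh, later=fresh.copy())


def batch_with_cvs(cv_factor: float, seed: int = 0) -> AlleyBatch:
    """Batch whose per-trait CV is exactly cv_factor x the acceptable CV.

    Points alternate mean +/- delta (8 each), so the sample CV is exact and
    no point exceeds the +/-2 SD trim (|z| = sqrt(15/16) < 2).
    """
    from tmrqc.indexes import DEFAULT_TRAIT_SPECS

    means = {"S4": 34.2, "S5": 17.9, "bottom": 17.8, "GMPL": 6.4,
             "CP": 15.2, "aNDF": 33.1, "starch": 26.0}
    data = {}
    for spec in DEFAULT_TRAIT_SPECS:
        m = means[spec.trait]
        target_cv = cv_factor * spec.acceptable_cv / 100.0
        delta = target_cv * m * np.sqrt(15.0 / 16.0)
        vals = np.empty(16)
        vals[::2] = m + delta
        vals[1::2] = m - delta
        data[spec.trait] = vals
    fresh = pd.DataFrame(data)[list(TRAIT_NAMES)]
    return AlleyBatch(fresh=fresh)
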