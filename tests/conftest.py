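import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from petrad.models import BIOCHEM_COLS
from petrad.pipeline import cohort_features
from petrad.synthetic_cohort import default_params, simulate_cohort, simulate_lesion


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def random_labels_6(rng):
    """Random 6^3 discretised region with 4 grey levels, fully in mask."""
    return rng.integers(1, 5, size=(6, 6, 6)).astype(np.int32)


@pytest.fixture(scope="session")
def random_labels_masked(rng):
    """8^3 region, irregular mask (0 = outside), 5 levels."""
    lab = rng.integers(1, 6, size=(8, 8, 8)).astype(np.int32)
    mask = rng.random((8, 8, 8)) < 0.7
    lab[~mask] = 0
    assert lab.max() > 0
    return lab


@pytest.fixture(scope="session")
def demo_lesion():
    return simulate_lesion("cluster2", default_params(), seed=5)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-lesion cohort for smoke-level pipeline tests."""
    return simulate_cohort(2, 2, 2, default_params(), seed=3)


@pytest.fixture(scope="session")
def cohort_table():
    """Full default 40-lesion cohort feature table (session-cached)."""
    lesions = simulate_cohort(13, 18, 9, default_params(), seed=1)
    return cohort_features(lesions)


@pytest.fixture(scope="session")
def synthetic_features():
    """Fast stand-in feature table (no imaging) for classifier unit tests.

    Three classes with a planted 1-D signal in a few 'PET_' columns plus
    pure-noise columns and biochemistry flags.
    """
    gen = np.random.default_rng(99)
    n_per = {"cluster1": 13, "cluster2": 18, "sporadic": 9}
    shift = {"cluster1": 2.5, "cluster2": 0.0, "sporadic": 0.7}
    rows, labels = [], []
    for cls, n in n_per.items():
        for _ in range(n):
            base = gen.normal(shift[cls], 1.0)
            row = {
                "PET_firstorder_Maximum": base + gen.normal(0, 0.3),
                "PET_firstorder_Entropy": 0.8 * base + gen.normal(0, 0.5),
                "PET_shape_Maximum3DDiameter": 0.6 * base + gen.normal(0, 0.7),
                "PET_glcm_ClusterShade": 0.5 * base + gen.normal(0, 0.8),
            }
            for i in range(8):
                row[f"PET_noise{i}"] = gen.normal()
            for i in range(6):
                row[f"CT_noise{i}"] = gen.normal()
            row.update({c: int(gen.random() < 0.4) for c in BIOCHEM_COLS})
            rows.append(row)
            labels.append(cls)
    df = pd.DataFrame(rows)
    df["cluster"] = labels
    return df
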