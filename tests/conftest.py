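from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from rhizomarker.dataio import FeatureTable
from rhizomarker.synthetic import SyntheticConfig, generate_feature_table

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def tiny_table_path() -> Path:
    return DATA_DIR / "tiny_feature_table.csv"


@pytest.fixture(scope="session")
def tiny_design_path() -> Path:
    return DATA_DIR / "tiny_design.csv"


def make_table(intensities, soil_types, mode="positive", mz=None, rt=None,
               solution=50):
    """Small hand-built FeatureTable for unit tests."""
    intensities = np.asarray(intensities, dtype=float)
    nf, ns = intensities.shape
    features = pd.DataFrame(
        {
            "mz": mz if mz is not None else np.linspace(100, 500, nf),
            "rt": rt if rt is not None else np.linspace(60, 600, nf),
            "mode": mode,
        },
        index=pd.Index([f"F{i:03d}" for i in range(nf)], name="feature_id"),
    )
    reps = {}
    sample_ids = []
    for s in soil_types:
        reps[s] = reps.get(s, 0) + 1
        sample_ids.append(f"{s}_{solution}_{reps[s]}")
    samples = pd.DataFrame(
        {
            "soil_type": list(soil_types),
            "solution": solution,
            "replicate": [int(sid.rsplit("_", 1)[1]) for sid in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return FeatureTable(features, samples, intensities)


@pytest.fixture(scope="session")
def default_synthetic():
    """One seeded table at the study design (5 plant vs 3 control)."""
    config = SyntheticConfig(n_features_per_mode=500, seed=42)
    return generate_feature_table(config, 50, "positive")
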