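import numpy as np
import pandas as pd
import pytest

from emospace import Configuration, RatingDataset
from emospace.reference import (
    load_reference_configuration,
    load_reference_model_distances,
    load_reference_profile_distances,
    load_reference_summary,
)


@pytest.fixture(scope="session")
def reference_summary():
    return load_reference_summary()


@pytest.fixture(scope="session")
def reference_configuration():
    return load_reference_configuration()


@pytest.fixture(scope="session")
def reference_profile_distances():
    return load_reference_profile_distances()


@pytest.fixture(scope="session")
def reference_model_distances():
    return load_reference_model_distances()


@pytest.fixture
def planted_configuration():
    """A centered 16-object 3D configuration with a fixed seed."""
    rng = np.random.default_rng(42)
    coords = rng.standard_normal((16, 3))
    coords -= coords.mean(axis=0)
    return Configuration([f"e{i:02d}" for i in range(16)], coords, centered=True)


@pytest.fixture
def toy_dataset():
    """5 participants × 4 emotions × 4 aspects with hand-enterable values."""
    rng = np.random.default_rng(3)
    values = rng.uniform(5, 95, size=(5, 4, 4))
    return RatingDataset(
        [f"p{i}" for i in range(5)],
        ["joy", "dread", "calm", "spite"],
        ["valence", "arousal", "control", "utility"],
        values,
    )


@pytest.fixture
def small_summary():
    """Two emotions, four aspects, known mean profiles."""
    rows = []
    profiles = {"a": (10.0, 20.0, 30.0, 40.0), "b": (13.0, 24.0, 30.0, 40.0)}
    for emo, means in profiles.items():
        for aspect, m in zip(("valence", "arousal", "control", "utility"), means):
            rows.append((emo, aspect, m, 5.0, 10))
    from emospace import AspectSummaryTable

    return AspectSummaryTable(
        pd.DataFrame(rows, columns=["emotion", "aspect", "mean", "sd", "n"])
    )
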