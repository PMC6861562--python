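import numpy as np
import pandas as pd
import pytest

from agedelta.synthetic import GeneratorConfig, generate_cohort


def make_cohort(ages, features, groups=None, prefix="S"):
    """Hand-built cohort table; ``features`` is (n, p)."""
    ages = np.asarray(ages, dtype=float)
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[0] != len(ages):
        features = features.T
    groups = ["CN"] * len(ages) if groups is None else list(groups)
    df = pd.DataFrame(
        {
            "subject_id": [f"{prefix}_{i:04d}" for i in range(len(ages))],
            "age": ages,
            "group": groups,
        }
    )
    for j in range(features.shape[1]):
        df[f"feat_{j + 1:04d}"] = features[:, j]
    return df


@pytest.fixture
def identity_cohort():
    """Single noiseless feature exactly equal to age."""
    ages = np.linspace(47, 94, 40)
    return make_cohort(ages, ages[:, None])


@pytest.fixture
def noisy_cohort():
    """Small cohort from the generator with real measurement noise."""
    cfg = GeneratorConfig(
        n_per_group={"CN": 120}, n_features=4, feature_noise_sd=30.0, seed=11
    )
    return generate_cohort(cfg)
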