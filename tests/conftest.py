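import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_matrix() -> pd.DataFrame:
    """A fixed 4-feature x 5-sample strictly positive matrix."""
    rng = np.random.default_rng(42)
    X = pd.DataFrame(
        rng.lognormal(mean=2.0, sigma=0.5, size=(4, 5)),
        index=["fA", "fB", "fC", "fD"],
        columns=[f"S{i}" for i in range(5)],
    )
    return X


@pytest.fixture(scope="session")
def planted():
    """The default planted dataset: 5 blocks x 30 features, 17 samples."""
    from mstknn import planted_expression

    return planted_expression(seed=0)


def random_positive_matrix(n_features: int, n_samples: int, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.lognormal(size=(n_features, n_samples)),
        index=[f"f{i:03d}" for i in range(n_features)],
        columns=[f"S{j:02d}" for j in range(n_samples)],
    )
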