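import numpy as np
import pandas as pd
import pytest

import tissuedecoder as td


@pytest.fixture(scope="session")
def small_cfg() -> td.SimulationConfig:
    """Six well-separated cell types, mild noise — the workhorse scenario."""
    return td.SimulationConfig(
        n_features=300,
        n_types=6,
        markers_per_type=10,
        marker_effect=8.0,
        replicates_per_type=5,
        noise_cv=0.05,
        n_mixtures=30,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_ref(small_cfg):
    ref, marker_truth = td.simulate_reference(small_cfg)
    return ref, marker_truth


@pytest.fixture(scope="session")
def small_signature(small_ref):
    ref, _ = small_ref
    return td.build_signature(ref, g_min=5, g_max=15)


@pytest.fixture()
def tiny_matrix() -> td.ExpressionMatrix:
    df = pd.DataFrame(
        {"s1": [1.0, 4.0, 100.0], "s2": [2.0, 5.0, 120.0]},
        index=["gA", "gB", "gC"],
    )
    return td.ExpressionMatrix(df)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
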