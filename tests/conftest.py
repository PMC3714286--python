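import numpy as np
import pandas as pd
import pytest

from ymrsig import SimulationConfig, load_default_signature, simulate_cohort


@pytest.fixture(scope="session")
def default_sig():
    return load_default_signature()


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced synthetic cohort for unit tests (fewer background features/samples)."""
    cfg = SimulationConfig(
        n_normal=40, n_tumor=160, n_background_features=300, seed=11
    )
    expr, clinical, truth = simulate_cohort(cfg)
    return expr, clinical, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_signature_matrix(rng, sig, n_samples=8, low=0.5, high=50.0):
    """Random positive expression matrix over the signature probes."""
    values = rng.uniform(low, high, size=(len(sig.genes), n_samples))
    return pd.DataFrame(
        values,
        index=[g.probe_id for g in sig.genes],
        columns=[f"S{i}" for i in range(n_samples)],
    )
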