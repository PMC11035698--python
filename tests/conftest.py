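import numpy as np
import pandas as pd
import pytest

from stressmeta.effect_sizes import compute_effect_table
from stressmeta.synthetic_data import SimulationConfig, fixture_library, simulate_dataset


@pytest.fixture(scope="session")
def fixtures():
    return fixture_library()


@pytest.fixture
def e1(fixtures):
    return fixtures["E1"]


@pytest.fixture
def e2(fixtures):
    return fixtures["E2"]


@pytest.fixture(scope="session")
def small_dataset():
    """A small hierarchical dataset with default (mild) heterogeneity."""
    cfg = SimulationConfig(
        n_studies=12, experiments_per_species=2, responses_per_experiment=2, seed=42
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_effects(small_dataset):
    experiments, _ = small_dataset
    return compute_effect_table(experiments)


def simulate_effect_rows(
    rng: np.random.Generator,
    k: int,
    n_studies: int,
    mu: float = 0.0,
    sigma_study: float = 0.0,
    sigma_resid: float = 0.0,
    v: float | np.ndarray = 0.01,
) -> pd.DataFrame:
    """Direct effect-level simulator (no factorial layer): y = mu + study
    effect + residual effect + sampling error, with known variance v.

    Used to probe the multilevel engine in isolation from the effect-size
    formulas.
    """
    study = np.repeat(np.arange(n_studies), -(-k // n_studies))[:k]
    v = np.broadcast_to(np.asarray(v, dtype=float), (k,))
    y = (
        mu
        + rng.normal(0.0, sigma_study, n_studies)[study]
        + rng.normal(0.0, sigma_resid, k)
        + rng.normal(0.0, np.sqrt(v))
    )
    return pd.DataFrame(
        {
            "value": y,
            "variance": v,
            "cluster_id": np.arange(k),
            "study_id": study,
            "effect_size_id": np.arange(k),
        }
    )
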