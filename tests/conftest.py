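import numpy as np
import pandas as pd
import pytest

from lipidratios.io import CohortTable, LipidomicsDataset, annotations_from_names
from lipidratios.simulate import GeneticConfig, SyntheticConfig, simulate_cohort


def make_dataset(values, species, batch=None, is_pqc=None, is_reference=None):
    """Small LipidomicsDataset from a plain array (samples x species)."""
    values = np.asarray(values, dtype=float)
    ids = [f"s{i}" for i in range(values.shape[0])]
    idx = pd.Index(ids)
    return LipidomicsDataset(
        concentrations=pd.DataFrame(values, index=idx, columns=species),
        annotations=annotations_from_names(species),
        batch=pd.Series(batch, index=idx) if batch is not None else None,
        is_pqc=pd.Series(is_pqc, index=idx) if is_pqc is not None else None,
        is_reference=pd.Series(is_reference, index=idx) if is_reference is not None else None,
    )


def make_cohort(n, seed=0, sex=None):
    rng = np.random.default_rng(seed)
    age = rng.normal(50, 10, n).clip(25)
    sex = rng.binomial(1, 0.5, n) if sex is None else np.asarray(sex)
    wc = 90 + 10 * rng.standard_normal(n)
    t = pd.DataFrame(
        {
            "age": age, "sex": sex, "WC": wc, "BMI": 2 + 0.28 * wc,
            "WHR": 0.35 + 0.0055 * wc, "total_cholesterol": rng.normal(5.5, 1, n),
            "disease_diabetes": rng.binomial(1, 0.1, n),
        },
        index=pd.Index([f"s{i}" for i in range(n)]),
    )
    return CohortTable(t)


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete synthetic configuration."""
    return SyntheticConfig(
        n_samples=(400, 300),
        n_species=60,
        n_classes=10,
        genetics=GeneticConfig(n_snps=400, n_chromosomes=4, ld_block_size=10),
        seed=1234,
    )


@pytest.fixture(scope="session")
def small_cohort_a(small_config):
    return simulate_cohort(small_config, cohort="a")


@pytest.fixture(scope="session")
def full_cohort():
    """Default-roster cohort (735 species, 39 classes) at reduced n."""
    config = SyntheticConfig(n_samples=(600, 100), genetics=None, seed=99)
    return simulate_cohort(config, cohort="a")
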