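import numpy as np
import pandas as pd
import pytest

import agesplice as ag


@pytest.fixture(scope="session")
def small_config():
    return ag.SimulationConfig(n_individuals=120, n_events=120, n_genes=40, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return ag.simulate_dataset(small_config)


def make_cohort(ages, genders=None, prefix="S"):
    """Hand-built cohort for direct model tests."""
    ages = np.asarray(ages, dtype=float)
    n = len(ages)
    if genders is None:
        genders = np.zeros(n, dtype=int)
    ids = [f"{prefix}{i:04d}" for i in range(n)]
    table = pd.DataFrame(
        {"donor_id": ids, "age": ages, "gender": np.asarray(genders, int)},
        index=pd.Index(ids, name="sample_id"),
    )
    return ag.Cohort(table)
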