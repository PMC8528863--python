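import numpy as np
import pytest

import mitopanel as mp


@pytest.fixture(scope="session")
def study():
    """One default study-sized cohort (27 samples, 137 proteins) with truth."""
    cfg = mp.SimConfig(seed=42)
    table, truth = mp.simulate_proteomics(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def study_samples(study):
    _, table, _ = study
    return mp.samples_from_meta(table.meta)


def unit_rms_columns(X):
    """Scale columns to unit root-mean-square (test helper for raw fits)."""
    s = np.sqrt((X**2).mean(axis=0))
    return X / s


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
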