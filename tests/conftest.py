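import numpy as np
import pandas as pd
import pytest

from microtrait import OtuTable, PhenotypeTable, SimulationConfig
from microtrait.simulate import simulate_community, simulate_traits


@pytest.fixture
def toy_table():
    """3 features x 4 samples count table with simple structure."""
    data = pd.DataFrame(
        [[10, 0, 5, 0],
         [5, 10, 0, 20],
         [5, 10, 15, 0]],
        index=["otuA", "otuB", "otuC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return OtuTable(data, kind="counts")


@pytest.fixture
def toy_pheno():
    rng = np.random.default_rng(0)
    n = 40
    frame = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "sex": np.where(rng.random(n) < 0.5, "castrated_boar", "gilt"),
        "batch": np.where(rng.random(n) < 0.5, "pen1", "pen2"),
        "GLU": rng.normal(3.0, 1.8, n),
        "TCHOL": rng.normal(2.2, 0.35, n),
        "TG": rng.normal(0.22, 0.1, n),
        "HDL": rng.uniform(0.5, 2.0, n),
        "LDL": rng.normal(1.5, 0.3, n),
    })
    return PhenotypeTable(frame)


@pytest.fixture(scope="session")
def small_cohort():
    """120-sample, 80-feature cohort with planted GLU effects; shared across
    tests that only read it."""
    cfg = SimulationConfig(n_samples=120, n_features=80, target_r2=0.3,
                           n_binary_effects=3, n_quant_effects=3,
                           n_both_effects=3, seed=42)
    table = simulate_community(cfg)
    pheno, truth = simulate_traits(table, cfg)
    return cfg, table, pheno, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Global-null cohort: no causal features, no covariate effects."""
    cfg = SimulationConfig(n_samples=100, n_features=60,
                           n_binary_effects=0, n_quant_effects=0,
                           n_both_effects=0, sex_effects={}, batch_sd=0.0,
                           seed=7)
    table = simulate_community(cfg)
    pheno, truth = simulate_traits(table, cfg)
    return cfg, table, pheno, truth
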