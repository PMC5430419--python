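import numpy as np
import pandas as pd
import pytest

from inversion_ee.synthetic_data import (
    SyntheticScenario,
    TraitSpec,
    generate_karyotype_dataset,
    generate_phenotype_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20170419)


@pytest.fixture
def toy_counts():
    """Two foundations x 2 replicates x 2 generations, one chromosome."""
    rows = []
    data = {
        ("F1", "R1", 2): {"O_ST": 30, "O_3+4": 70},
        ("F1", "R2", 2): {"O_ST": 40, "O_3+4": 60},
        ("F1", "R1", 25): {"O_ST": 10, "O_3+4": 90},
        ("F1", "R2", 25): {"O_ST": 15, "O_3+4": 85},
        ("F2", "R1", 2): {"O_ST": 80, "O_3+4": 20},
        ("F2", "R2", 2): {"O_ST": 75, "O_3+4": 25},
        ("F2", "R1", 25): {"O_ST": 60, "O_3+4": 40},
        ("F2", "R2", 25): {"O_ST": 55, "O_3+4": 45},
    }
    for (fnd, rep, gen), counts in data.items():
        for arr, c in counts.items():
            rows.append({
                "foundation": fnd, "replicate": rep, "generation": gen,
                "chromosome": "O", "arrangement": arr, "count": c,
            })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def neutral_dataset():
    """Small neutral synthetic dataset reused by read-only tests."""
    scenario = SyntheticScenario(seed=11)
    counts, truth = generate_karyotype_dataset(scenario)
    return scenario, counts, truth


@pytest.fixture(scope="session")
def pheno_dataset():
    scenario = SyntheticScenario(
        seed=7,
        trait_specs={
            "F1-7": TraitSpec(control_mean=180.0, initial_offset=-60.0, convergence=0.10, residual_sd=20.0),
            "RF": TraitSpec(control_mean=60.0, initial_offset=15.0, convergence=0.08, residual_sd=6.0),
        },
    )
    return scenario, generate_phenotype_dataset(scenario)
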