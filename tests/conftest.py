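import numpy as np
import pandas as pd
import pytest

from gepnet.simulate import ModuleSpec, SyntheticConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One-cell-type cohort with 3 planted programs, Poisson noise."""
    cfg = SyntheticConfig(
        n_samples=12,
        group_sizes={"HC": 3, "Inactive": 3, "Active": 3, "TreatmentNaive": 3},
        n_cell_types=1,
        genes_per_type=300,
        programs_per_type=3,
        cells_per_sample_per_type=40,
        overdispersion=0.0,
        activity_effect=0.0,
        module_spec=[ModuleSpec(1, [("B", 1), ("B", 2)], rho=0.7)],
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def multi_type_cohort():
    """Three cell types with a cross-cell-type module and activity effect."""
    cfg = SyntheticConfig(
        n_samples=27,
        group_sizes={"HC": 5, "Inactive": 6, "Active": 7,
                     "TreatmentNaive": 9},
        n_cell_types=3,
        genes_per_type=300,
        programs_per_type=3,
        cells_per_sample_per_type=30,
        overdispersion=0.3,
        activity_effect=2.0,
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
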