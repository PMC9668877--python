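import numpy as np
import pandas as pd
import pytest

from methnet import synthetic as syn


@pytest.fixture(scope="session")
def cohort():
    """Default-condition cohort at the study's sample size."""
    config = syn.CohortConfig(seed=11)
    pheno, truth = syn.simulate_phenotypes(config)
    return config, pheno, truth


@pytest.fixture(scope="session")
def small_methylome(cohort):
    """Compact methylome (300 probes, 3 planted modules) for fast tests."""
    _, pheno, truth = cohort
    config = syn.MethylomeConfig(
        n_probes=300,
        module_sizes=(15, 15, 15),
        seed=23,
        planted_mediation=syn.PlantedMediation(
            exposure="ctq", module_index=0, outcome="rmfg_sa",
            a_path=0.35, b_path=-0.45, c_prime=-0.10,
        ),
    )
    import dataclasses

    return syn.simulate_methylome(pheno, config, dataclasses.replace(truth))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
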