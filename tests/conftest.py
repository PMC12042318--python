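import numpy as np
import pandas as pd
import pytest

from omicweaver.io_core import ExpressionMatrix, SampleTable
from omicweaver.synthetic import CohortConfig, generate_cohort


def small_config(**overrides) -> CohortConfig:
    """A reduced cohort used across tests: one region, 300 proteins."""
    base = dict(
        n_per_group=10, regions=("DLPFC",), n_proteins=300, n_genes=400,
        n_mirnas=60, n_modules=4, module_size_min=20, module_size_max=30,
        n_de_proteins=15, n_de_genes=20, n_de_shared=10,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config(), seed=11)


@pytest.fixture()
def tiny_samples():
    n = 12
    rng = np.random.default_rng(5)
    return SampleTable(pd.DataFrame(dict(
        sample_id=[f"S{i}" for i in range(n)],
        donor_id=[f"D{i}" for i in range(n)],
        dx=["CON"] * 6 + ["PTSD"] * 6,
        region="DLPFC",
        sex=rng.choice(["M", "F"], n),
        age=rng.uniform(30, 70, n).round(1),
        ancestry="EUR",
        pmi=rng.uniform(10, 30, n).round(1),
        rin=rng.uniform(6, 9, n).round(2),
    )))


def gaussian_matrix(G, n, seed=0, modality="protein_log_intensity"):
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(
        [f"F{i}" for i in range(G)], [f"S{j}" for j in range(n)],
        rng.normal(7, 1, (G, n)), modality,
    )
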