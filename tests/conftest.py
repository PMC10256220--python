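import numpy as np
import pandas as pd
import pytest

from lumastrat import SimulationConfig, generate_tumor_cohort
from lumastrat.types import ExpressionMatrix, SurvivalTable


@pytest.fixture(scope="session")
def small_config():
    """200-gene, 150-sample cohort with strong subgroup separation."""
    return SimulationConfig(
        n_genes=200, n_samples=150, module_count=3, module_size=30, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_tumor_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_expression(values, gene_ids=None, sample_ids=None, scale_tag="zscore"):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), scale_tag=scale_tag
    )


def make_survival(time, event, sample_ids=None):
    time = np.asarray(time, dtype=float)
    sample_ids = sample_ids or [f"s{j}" for j in range(len(time))]
    return SurvivalTable(sample_ids, time, np.asarray(event))
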