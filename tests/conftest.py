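import numpy as np
import pandas as pd
import pytest

import stagedfs as s
from stagedfs.integrate import IntegrativeDataset


@pytest.fixture(scope="session")
def sim_config():
    return s.SimulationConfig(
        n_tumor=60, n_normal=20, n_genes=300, n_drivers=10, seed=11
    )


@pytest.fixture(scope="session")
def sim_data(sim_config):
    """(ExpressionMatrix, GroundTruth, records) from one small simulation."""
    expr, truth = s.simulate_expression(sim_config)
    records = s.simulate_mutations(sim_config, truth, expr.tumor_samples())
    return expr, truth, records


@pytest.fixture(scope="session")
def dataset(sim_data):
    """Integrative dataset built through the full front pipeline."""
    expr, truth, records = sim_data
    matrix = s.build_mutation_matrix(records)
    selection = s.filter_by_frequency(matrix, 0.01)
    norm = s.normalize_log2cpm(s.filter_low_expression(expr))
    return s.build_integrative_dataset(norm, selection)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, sim_data):
    expr, truth, records = sim_data
    d = tmp_path_factory.mktemp("fixture")
    s.write_fixture(d, expr, records, truth)
    return d


def make_dataset(values: np.ndarray, labels, genes=None, samples=None) -> IntegrativeDataset:
    """Hand-built integrative dataset (values already on the log2-CPM scale)."""
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return IntegrativeDataset(
        values=pd.DataFrame(values, index=genes, columns=samples),
        labels=pd.Series(list(labels), index=samples),
    )


@pytest.fixture
def toy_dataset():
    """Two genes over 8 samples with an obvious tumor/normal difference."""
    rng = np.random.default_rng(0)
    up = np.r_[rng.normal(8, 0.1, 5), rng.normal(4, 0.1, 3)]
    flat = rng.normal(5, 0.1, 8)
    return make_dataset(np.vstack([up, flat]), [1] * 5 + [0] * 3)
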