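import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from panelqc import ExpressionMatrix, SimConfig, simulate_dataset
from panelqc.pipeline import preprocess_counts


@pytest.fixture
def small_counts():
    """3-gene, 2-sample counts matrix with lengths, for normalization math."""
    values = pd.DataFrame(
        {"s1": [100.0, 100.0, 0.0], "s2": [10.0, 30.0, 60.0]},
        index=["g1", "g2", "g3"],
    )
    lengths = pd.Series([1000.0, 2000.0, 500.0], index=values.index)
    return ExpressionMatrix(values=values, unit="counts", gene_lengths=lengths)


@pytest.fixture
def panel_tsv(tmp_path):
    """Factory writing a panel table from a list of row dicts."""

    def _write(rows, name="panel.tsv", columns=None):
        cols = columns or [
            "symbol",
            "gene_id",
            "categories",
            "excluded_high_expression",
            "excluded_no_primer",
        ]
        path = tmp_path / name
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
        return path

    return _write


@pytest.fixture(scope="session")
def sim_default():
    """One default simulated dataset (seed 0), shared across tests."""
    return simulate_dataset(SimConfig(seed=0))


@pytest.fixture(scope="session")
def sim_logtpm(sim_default):
    return preprocess_counts(sim_default.counts)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
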