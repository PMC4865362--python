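import pandas as pd
import pytest
from hypothesis import settings

from hydroxymeta import CallTable, GeneModel, SimulationConfig, simulate_dataset

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

THREE_ROWS = pd.DataFrame(
    {
        "chrom": ["chr1", "chr1", "chr2"],
        "pos": [10, 25, 3],
        "strand": ["+", "-", "+"],
        "context": ["CG", "CHH", "CG"],
        "protected": [2, 0, 5],
        "total": [7, 4, 5],
    }
)


@pytest.fixture
def three_row_table():
    return CallTable("fixture", "genome", THREE_ROWS.copy())


@pytest.fixture
def three_row_file(tmp_path):
    path = tmp_path / "calls.tsv"
    THREE_ROWS.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def five_genes():
    return [
        GeneModel("gA", "chr1", "+", 1000, 2000, 800),
        GeneModel("gB", "chr1", "-", 3000, 4000, 500),
        GeneModel("gC", "chr1", "+", 5000, 5100, 100),
        GeneModel("gD", "chr2", "-", 100, 700, 600),
        GeneModel("gE", "chr2", "+", 900, 2000, 300),
    ]


@pytest.fixture(scope="session")
def small_config():
    """Small but non-trivial simulation: 40 genes on 2 x 120 kb at 2x."""
    return SimulationConfig(
        seed=7, chrom_lengths=(120_000, 120_000), n_genes=40, coverage=2.0
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)
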