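import numpy as np
import pandas as pd
import pytest

from hetexpr.quantify import ExpressionTable
from hetexpr.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study shared by read-only tests."""
    cfg = SimulationConfig(n_genes=300, library_size=300_000, seed=42)
    return simulate_study(cfg)


@pytest.fixture()
def tiny_expression():
    """A hand-sized expression table with three samples."""
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.integers(0, 500, size=(20, 3)),
        columns=["H", "P1", "P2"],
        index=pd.Index([f"t{i:02d}" for i in range(20)], name="transcript_id"),
    )
    lengths = pd.Series(rng.integers(300, 3000, size=20), index=counts.index)
    gene_ids = pd.Series([f"g{i // 2:02d}" for i in range(20)], index=counts.index)
    return ExpressionTable.from_counts(counts, lengths, gene_ids)
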