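import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from circuitmarkers.datasets import ExpressionDataset
from circuitmarkers.simulate import SynthConfig, generate_counts

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_synth():
    """Small planted dataset shared by engine tests (fast, deterministic)."""
    config = SynthConfig(n_cells_per_group=60, n_genes=120, seed=7)
    return generate_counts(config)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A handful of cells with hand-set counts for exact checks."""
    rng = np.random.default_rng(0)
    genes = np.array([f"g{i}" for i in range(5)], dtype=object)
    cells = []
    for region in ("ALM", "VISp"):
        for cls in ("L2/3 IT", "L5 IT", "L5 PT", "L6 CT", "VIP", "SST", "PV"):
            for i in range(3):
                tag = cls.replace("/", "").replace(" ", "")
                cells.append((f"{region}_{tag}_{i}", region, cls))
    cells = pd.DataFrame(cells, columns=["cell_id", "region", "class"])
    counts = rng.integers(1, 20, size=(len(genes), len(cells)))
    return ExpressionDataset(counts, genes, cells)
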