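import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from giena import ExpressionDataset, SignalSpec, generate


@pytest.fixture(scope="session")
def small_null_dataset():
    """40 genes x (5 case + 5 control), pure noise, 4 pathways."""
    ds, gsc, truth = generate(
        n_genes=40, n_case=5, n_control=5, pathways=4,
        genes_per_pathway=(6, 8), signals=[], seed=101,
    )
    return ds, gsc, truth


@pytest.fixture(scope="session")
def signal_dataset():
    """One cooperation-dysregulated pathway among nulls, 20 vs 20."""
    ds, gsc, truth = generate(
        n_genes=120, n_case=20, n_control=20, pathways=8,
        genes_per_pathway=(10, 10),
        signals=[SignalSpec("PW001", "cooperation", 10, 2.0)],
        seed=7,
    )
    return ds, gsc, truth


@pytest.fixture()
def tiny_dataset():
    """Hand-built 4-gene, 4+4-sample dataset with known values."""
    rng = np.random.default_rng(42)
    values = rng.normal(size=(4, 8))
    return ExpressionDataset(
        genes=["GA", "GB", "GC", "GD"],
        samples=[f"s{i}" for i in range(8)],
        values=values,
        labels=np.array(["control"] * 4 + ["case"] * 4, dtype=object),
    )
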