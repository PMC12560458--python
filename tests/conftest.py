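import numpy as np
import pandas as pd
import pytest

from gscresist.config import CohortConfig


@pytest.fixture
def small_cohort() -> CohortConfig:
    """A cohort small enough for fast end-to-end runs."""
    return CohortConfig(n_drugs=30, n_genes=200, n_islands=60, seed=42)


@pytest.fixture
def labels_9():
    """Planted labels of the default 4-sensitive / 5-resistant design."""
    samples = [f"GSC-S{i:02d}" for i in (1, 2, 3, 4)] + [
        f"GSC-R{i:02d}" for i in (1, 2, 3, 4, 5)]
    groups = ["sensitive"] * 4 + ["resistant"] * 5
    return pd.DataFrame({"group": groups},
                        index=pd.Index(samples, name="sample"))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
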