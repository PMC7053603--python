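import numpy as np
import pandas as pd
import pytest

from cernet.diffexpr import ExpressionDataset
from cernet.synthetic import SimulationConfig, generate_study


def paired_dataset(values, kind="mRNA", dataset_id="ds1"):
    """Build a paired tumor/normal dataset from a features x samples array.

    Columns alternate tumor, normal per subject.
    """
    values = np.asarray(values, dtype=float)
    n_pairs = values.shape[1] // 2
    cols = [f"s{p}_{c}" for p in range(n_pairs) for c in ("T", "N")]
    meta = pd.DataFrame({
        "sample_id": cols,
        "subject_id": [f"s{p}" for p in range(n_pairs) for _ in range(2)],
        "condition": ["tumor", "normal"] * n_pairs,
    })
    matrix = pd.DataFrame(values, columns=cols,
                          index=[f"f{i}" for i in range(values.shape[0])])
    return ExpressionDataset(dataset_id, kind, matrix, meta, "paired")


@pytest.fixture(scope="session")
def default_bundle():
    """One default-condition synthetic study bundle, shared across tests."""
    return generate_study(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_config():
    """A reduced bundle for fast repeated generation."""
    return SimulationConfig(n_mrna=12, n_lncrna=8, n_mirna=6,
                            n_planted_triples=3, n_planted_de_singletons=2,
                            n_pairs_per_dataset=(8, 8), seed=7)
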