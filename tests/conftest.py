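import numpy as np
import pandas as pd
import pytest

from tmtqc import AbundanceMatrix, SampleMetadata, SimulationConfig, simulate_cohort
from tmtqc.containers import METADATA_COLUMNS


def make_matrix(values, stage="log2", protein_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    protein_ids = protein_ids or [f"p{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return AbundanceMatrix(pd.DataFrame(values, index=protein_ids, columns=sample_ids),
                           stage=stage)


def make_metadata(sample_ids, **columns):
    """Metadata frame with sensible defaults for unspecified trait columns."""
    n = len(sample_ids)
    defaults = {
        "individual_id": list(sample_ids),
        "batch": ["b1"] * n,
        "site": ["siteA"] * n,
        "sex": ["female"] * n,
        "race": ["NHW"] * n,
        "diagnosis": ["control"] * n,
        "age": [75.0] * n,
        "cerad": [1] * n,
        "braak": [2] * n,
        "apoe": ["e3/e3"] * n,
    }
    defaults.update(columns)
    df = pd.DataFrame(defaults, index=pd.Index(sample_ids, name="sample_id"))
    return SampleMetadata(df[list(METADATA_COLUMNS)])


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic desk-scale cohort with planted structure, reused read-only."""
    cfg = SimulationConfig(seed=11, n_proteins=200, n_samples=160, n_batches=8,
                           n_sites=4, n_outliers=0, missing_rate_target=0.0)
    matrix, metadata, truth = simulate_cohort(cfg)
    return cfg, matrix, metadata, truth
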