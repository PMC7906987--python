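from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from crosstalk.datatypes import AnalysisConfig, ExpressionDataset

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


def make_dataset(values, dataset_id="ds1", compartment="tubule", n_case=None,
                 patients=None, genes=None):
    """Small helper: wrap a 2-D array into a validated ExpressionDataset."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes if genes is not None else [f"g{i}" for i in range(n_genes)]
    samples = [f"{dataset_id}_s{j}" for j in range(n_samples)]
    n_case = n_samples // 2 if n_case is None else n_case
    group = pd.Series(["case"] * n_case + ["control"] * (n_samples - n_case),
                      index=samples)
    patient = pd.Series(patients, index=samples) if patients is not None else None
    return ExpressionDataset(
        dataset_id=dataset_id,
        values=pd.DataFrame(values, index=genes, columns=samples),
        compartment=compartment,
        group=group,
        patient_id=patient,
    ).validate()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def config():
    return AnalysisConfig().validate()
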