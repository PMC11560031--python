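"""Shared fixtures: toy matrices and one default synthetic dataset."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from refstab.io_qpcr import CqMatrix, collapse_technical_replicates, impute_or_drop
from refstab.simulate import default_truth, simulate_cq
from refstab.subsets import apply_subset, standard_subsets


def toy_frame(array, genes=None, samples=None) -> pd.DataFrame:
    """genes x samples Cq DataFrame from a plain array."""
    a = np.asarray(array, dtype=float)
    genes = genes or [f"G{i}" for i in range(a.shape[0])]
    samples = samples or [f"s{j}" for j in range(a.shape[1])]
    return pd.DataFrame(a, index=genes, columns=samples)


def toy_cqmatrix(array, genes=None, samples=None, annotation=None) -> CqMatrix:
    """CqMatrix with placeholder annotation for algorithm-level tests."""
    values = toy_frame(array, genes, samples)
    if annotation is None:
        annotation = pd.DataFrame(
            {
                "strain": "BL10-wt",
                "genotype": "healthy",
                "age_weeks": 4,
                "muscle": "GC",
                "animal": 1,
            },
            index=values.columns,
        )
    return CqMatrix(values, annotation)


@pytest.fixture(scope="session")
def truth():
    return default_truth(seed=7)


@pytest.fixture(scope="session")
def cq_table(truth):
    return simulate_cq(truth)


@pytest.fixture(scope="session")
def full_matrix(cq_table):
    """Collapsed full-design matrix (10 gene rows, 180 samples)."""
    return collapse_technical_replicates(cq_table)


@pytest.fixture(scope="session")
def entire_matrix(full_matrix):
    """Complete core-8 matrix over all 180 samples."""
    spec = next(s for s in standard_subsets(full_matrix) if s.label == "entire")
    return impute_or_drop(apply_subset(full_matrix, spec), "drop_sample")
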