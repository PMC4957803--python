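import numpy as np
import pandas as pd
import pytest

from mirdep import (
    ExpressionMatrix,
    GeneratorParams,
    contrast,
    generate_expression,
    join_sample_sheet,
)
from mirdep.datasets import mir155


@pytest.fixture(scope="session")
def mir():
    return mir155()


@pytest.fixture(scope="session")
def small_study():
    """A small planted study shared by read-only tests (seed fixed)."""
    params = GeneratorParams(n_probes=1000, n_targets=15, seed=11)
    return generate_expression(params)


@pytest.fixture(scope="session")
def small_contrasts(small_study):
    matrix, _, _ = small_study
    return {
        "wt": contrast(matrix, ("WT", "M1"), ("WT", "M0")),
        "ko": contrast(matrix, ("KO", "M1"), ("KO", "M0")),
        "cross_ko": contrast(matrix, ("KO", "M1"), ("WT", "M1")),
        "cross_wt": contrast(matrix, ("WT", "M1"), ("KO", "M1")),
    }


def toy_matrix(values, probes=None, samples=None, sheet=None):
    """Build a (optionally annotated) ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    matrix = ExpressionMatrix(values=pd.DataFrame(values, index=probes, columns=samples))
    if sheet is not None:
        matrix = join_sample_sheet(matrix, sheet)
    return matrix


def group_sheet(assignments):
    """Sample sheet from {sample_id: (genotype, condition)}."""
    return pd.DataFrame(
        {
            "genotype": [gt for gt, _ in assignments.values()],
            "condition": [c for _, c in assignments.values()],
        },
        index=pd.Index(list(assignments), name="sample_id"),
    )
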