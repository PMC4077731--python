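import numpy as np
import pandas as pd
import pytest

from aktsubtypes import (
    CohortConfig,
    ConsensusParams,
    ExpressionMatrix,
    generate_cohort,
    median_center,
    select_panel,
    subset_to_panel,
)


@pytest.fixture(scope="session")
def small_cohort():
    """n=60, 300 genes, 3 well-separated planted subtypes."""
    return generate_cohort(CohortConfig(n_samples=60, n_genes=300, seed=11))


@pytest.fixture(scope="session")
def small_panel_matrix(small_cohort):
    centered = median_center(small_cohort.expression)
    panel = select_panel(centered, list(small_cohort.truth_panel))
    return subset_to_panel(centered, panel)


@pytest.fixture(scope="session")
def fast_params():
    return ConsensusParams(n_iter=100, subsample_frac=0.8, seed=5)


def make_matrix(values, genes=None, samples=None, centered=False) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), centered=centered)
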