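import numpy as np
import pandas as pd
import pytest

from bastage import FIBROSIS, INFLAMMATION, SimConfig, simulate_cohort
from bastage.histology import (
    assign_histology_groups,
    groups_to_frame,
    scores_from_table,
)


@pytest.fixture(scope="session")
def study_cohort():
    """47-sample cohort with a 9-vs-5 histology seed subset and known truth."""
    return simulate_cohort(SimConfig(rng_seed=0, seed_group_counts=(9, 5)))


@pytest.fixture(scope="session")
def seed_groups(study_cohort):
    """Histology seed groups (threshold 2) of the session cohort."""
    groups, _ = assign_histology_groups(
        scores_from_table(study_cohort.samples), threshold=2
    )
    frame = groups_to_frame(groups)
    return {
        INFLAMMATION: list(frame.loc[frame.label == INFLAMMATION, "subject_id"]),
        FIBROSIS: list(frame.loc[frame.label == FIBROSIS, "subject_id"]),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_matrix(rng):
    """Random 30-probe x 10-sample log2 matrix with labelled halves."""
    X = rng.normal(7.0, 1.0, size=(30, 10))
    matrix = pd.DataFrame(
        X,
        index=[f"P{i:03d}" for i in range(30)],
        columns=[f"S{j:02d}" for j in range(10)],
    )
    labels = pd.Series(
        [INFLAMMATION] * 5 + [FIBROSIS] * 5, index=matrix.columns
    )
    return matrix, labels
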