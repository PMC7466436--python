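import numpy as np
import pytest

from cohmetrics import (
    DocFrequencyTable,
    SimConfig,
    WordVectorTable,
    extract_cohort_features,
    read_dictionary,
    simulate_cohort,
)
from importlib import resources


@pytest.fixture(scope="session")
def tiny_vectors() -> WordVectorTable:
    return WordVectorTable(
        dimension=2,
        entries={
            "angst": np.array([1.0, 0.0]),
            "ist": np.array([0.0, 1.0]),
            "haus": np.array([1.0, 1.0]),
            "trauer": np.array([0.6, 0.8]),
        },
    )


@pytest.fixture(scope="session")
def tiny_df() -> DocFrequencyTable:
    return DocFrequencyTable(
        total_documents=1000, counts={"angst": 10, "ist": 500, "haus": 10}
    )


@pytest.fixture(scope="session")
def demo_dictionary():
    path = resources.files("cohmetrics").joinpath("data", "demo_categories.dic")
    return read_dictionary(str(path))


@pytest.fixture(scope="session")
def small_cohort():
    """Compact seeded cohort (6 per group, 3 sentences per answer)."""
    return simulate_cohort(
        SimConfig(
            seed=42,
            group_sizes={"HC": 6, "NAP_FTD": 6, "NAP_noFTD": 6},
            sentences_per_answer=3,
        )
    )


@pytest.fixture(scope="session")
def study_cohort():
    """One cohort at the study's default size (20 per group)."""
    return simulate_cohort(SimConfig(seed=42))


@pytest.fixture(scope="session")
def study_features(study_cohort, demo_dictionary):
    return extract_cohort_features(
        study_cohort.transcripts,
        study_cohort.vectors,
        study_cohort.df_table,
        annotations=study_cohort.annotations,
        clinical=study_cohort.clinical,
        dictionary=demo_dictionary,
    )


@pytest.fixture(scope="session")
def small_features(small_cohort, demo_dictionary):
    return extract_cohort_features(
        small_cohort.transcripts,
        small_cohort.vectors,
        small_cohort.df_table,
        annotations=small_cohort.annotations,
        clinical=small_cohort.clinical,
        dictionary=demo_dictionary,
    )
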