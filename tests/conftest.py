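import numpy as np
import pandas as pd
import pytest

from crossfence.synthetic_data import (
    default_population_specs,
    gen_landmarks,
    gen_specimens,
)


@pytest.fixture(scope="session")
def study_records() -> pd.DataFrame:
    """One synthetic draw of the two-population study sample (115 + 51)."""
    return gen_specimens(default_population_specs(exact_sex_counts=True), seed=11)


@pytest.fixture(scope="session")
def small_records(study_records) -> pd.DataFrame:
    """A 40-specimen subsample for morphometric tests (stratified by sex)."""
    return (
        study_records.groupby(["property", "sex"], group_keys=False)
        .head(10)
        .reset_index(drop=True)
    )


@pytest.fixture(scope="session")
def small_landmarks(small_records):
    return gen_landmarks(small_records, template_k=12, allometric_vector_scale=0.15,
                         asym_sd=0.002, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
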