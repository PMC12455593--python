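import warnings

import numpy as np
import pandas as pd
import pytest

from visionair import (
    GradientBoostedTrees,
    derive_labels,
    encode_features,
    generate_cohort,
    load_generative_spec,
    load_schema,
)


@pytest.fixture(scope="session")
def schema():
    return load_schema()


@pytest.fixture(scope="session")
def default_spec():
    return load_generative_spec("default")


@pytest.fixture(scope="session")
def cohort_small(default_spec):
    """2,000-row default synthetic cohort, id-indexed."""
    table = generate_cohort(default_spec.model_copy(update={"n": 2000}), seed=11)
    return table.set_index(pd.Index(table["id"], name="row_id"), drop=False)


@pytest.fixture(scope="session")
def labels_small(cohort_small):
    return derive_labels(cohort_small)


@pytest.fixture(scope="session")
def encoded_small(cohort_small, schema):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return encode_features(cohort_small, schema=schema)


@pytest.fixture(scope="session")
def gbm_small(cohort_small, encoded_small):
    """GBM fitted on the small cohort (all rows; fixture for explanation tests)."""
    model = GradientBoostedTrees(
        n_trees=150, depth=4, categorical_features=encoded_small.categorical, random_state=0
    )
    model.fit(encoded_small.X, cohort_small["ucva"])
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
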