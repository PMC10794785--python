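import numpy as np
import pandas as pd
import pytest

from xydosage import dosage_model as dm
from xydosage import synthetic_data as sd


@pytest.fixture(scope="session")
def lcl_meta():
    return sd.generate_design(sd.LCL_DESIGN, seed=1)


@pytest.fixture(scope="session")
def small_truth():
    return sd.generate_truth(600, seed=2)


@pytest.fixture(scope="session")
def small_counts(lcl_meta, small_truth):
    return sd.generate_counts(lcl_meta, small_truth, seed=3)


@pytest.fixture(scope="session")
def annotation(small_truth):
    return sd.generate_annotation(small_truth, seed=4)


@pytest.fixture(scope="session")
def small_fit(small_counts, lcl_meta):
    return dm.fit_dosage_glm(small_counts, lcl_meta)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
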