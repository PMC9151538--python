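import numpy as np
import pytest

from rflesion import study_data


@pytest.fixture(scope="session")
def area_table():
    return study_data.load_lesion_area_table()


@pytest.fixture(scope="session")
def depth_table():
    return study_data.load_lesion_depth_table()


@pytest.fixture(scope="session")
def ratio_table():
    return study_data.load_ratio_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
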