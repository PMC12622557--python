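import numpy as np
import pytest

from pomscout.bo import Dimension, SearchSpace
from pomscout.keggin import build_ideal_keggin, enumerate_framework_faces
from pomscout.synthetic import build_residue


@pytest.fixture(scope="session")
def gly():
    return build_residue("Gly")


@pytest.fixture(scope="session")
def keggin():
    return build_ideal_keggin()


@pytest.fixture(scope="session")
def keggin_faces(keggin):
    return enumerate_framework_faces(keggin)


@pytest.fixture()
def box_space_2d():
    return SearchSpace(
        dims=[Dimension(f"x{i}", "generic", 0.0, 10.0, False) for i in range(2)]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
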