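import numpy as np
import pytest

from ampdel.errors import ErrorModel
from ampdel.references import build_reference, plant_microhomology


@pytest.fixture(scope="session")
def amplicon():
    """A 5 kb reference with an MMEJ-competent microhomology at the cut."""
    ref = build_reference(5000, seed=11, cut_site=2500, name="locusA")
    ref, mmej_start = plant_microhomology(ref)
    return ref, mmej_start


@pytest.fixture(scope="session")
def small_amplicon():
    return build_reference(1200, seed=21, cut_site=600, name="mini")


@pytest.fixture(scope="session")
def error_model():
    return ErrorModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
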