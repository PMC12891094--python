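import matplotlib
import pytest

matplotlib.use("Agg")

from hypothesis import settings

settings.register_profile("ci", deadline=None, max_examples=50)
settings.load_profile("ci")

from progmat import build_matrix, cof, make_primitive, mat_apply
from progmat.fixtures import tutorial_item


@pytest.fixture
def square():
    return make_primitive("square")


@pytest.fixture
def shape_triple():
    return cof(make_primitive("hexagon"), make_primitive("pentagon"),
               make_primitive("square"))


@pytest.fixture
def shape_matrix(shape_triple):
    return mat_apply(shape_triple, hrules=["shape"])


@pytest.fixture
def tutorial_matrix():
    return build_matrix(tutorial_item())
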