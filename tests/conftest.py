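import numpy as np
import pytest

from bdmshift.io import ProteinAlignment, read_newick_string
from bdmshift.models import discretize_gamma, load_model


@pytest.fixture(scope="session")
def wag():
    return load_model("WAG")


@pytest.fixture(scope="session")
def jtt():
    return load_model("JTT")


@pytest.fixture(scope="session")
def gamma2():
    return discretize_gamma(1.1990, 2)


@pytest.fixture
def quartet_tree():
    return read_newick_string("((A:0.12,B:0.31):0.07,(C:0.22,D:0.09):0.15);")


@pytest.fixture
def quartet_alignment(wag):
    rng = np.random.default_rng(7)
    rows = [
        "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=3)) for _ in range(4)
    ]
    return ProteinAlignment(names=["A", "B", "C", "D"], rows=rows)
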