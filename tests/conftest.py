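import numpy as np
import pytest

from ampedit import hbb_demo_locus


@pytest.fixture(scope="session")
def locus():
    return hbb_demo_locus()


@pytest.fixture(scope="session")
def minus_locus(locus):
    return locus.reverse_complemented()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))
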