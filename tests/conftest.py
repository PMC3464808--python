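import numpy as np
import pytest

from tsplasmid.burial import EISENBERG_CONSENSUS, STANDARD_AA, HydrophobicityScale
from tsplasmid.datasets import load_codon_usage, repb_screen_records


@pytest.fixture(scope="session")
def usage():
    return load_codon_usage()


@pytest.fixture(scope="session")
def screen_records():
    return repb_screen_records()


@pytest.fixture
def toy_scale():
    """H(A)=1, H(D)=-2, everything else 0 — keeps hand arithmetic easy."""
    values = {aa: 0.0 for aa in STANDARD_AA}
    values["A"] = 1.0
    values["D"] = -2.0
    return HydrophobicityScale(name="toy", values=values)


@pytest.fixture
def eisenberg():
    return EISENBERG_CONSENSUS


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_protein(rng, n):
    return "".join(rng.choice(list(STANDARD_AA), size=n))
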