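import pytest

from qsppred.features import EncodingSpec
from qsppred.fixtures import FixtureSpec, generate, make_separable
from qsppred.model import CVConfig
from qsppred.seqio import NEGATIVE, POSITIVE, Peptide, PeptideSet


@pytest.fixture(scope="session")
def small_sets():
    """Small seeded QSP-like / non-QSP-like sets for fast tests."""
    return generate(FixtureSpec(n_pos=40, n_neg=40, seed=11))


@pytest.fixture(scope="session")
def full_sets():
    """Study-sized (220+220) synthetic sets."""
    return generate(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def separable():
    return make_separable(n=400, seed=3)


@pytest.fixture(scope="session")
def quick_cv():
    """Coarse hyper-parameter grid to keep CV tests fast."""
    return CVConfig(n_folds=10, seed=3, c_grid=(1.0, 8.0), g_grid=(0.1, 1.0))


@pytest.fixture
def toy_set():
    return PeptideSet(
        [
            Peptide("p1", "SGSLSTFFRLFNRSFTQA", POSITIVE),
            Peptide("p2", "ACDEFGHIKL", POSITIVE),
            Peptide("n1", "GGGGGGG", NEGATIVE),
        ],
        name="toy",
    )


@pytest.fixture
def aac_spec():
    return EncodingSpec("AAC")
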