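import warnings

import numpy as np
import pytest

from trimology.fixtures import generate_fixture_locus
from trimology.predictor import SurrogatePredictor
from trimology.seqcore import SequenceRecord, find_cut_sites

warnings.filterwarnings("ignore", module="Bio")

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240923)


@pytest.fixture(scope="session")
def surrogate():
    return SurrogatePredictor()


@pytest.fixture(scope="session")
def fixture_locus():
    """Synthetic 2-kb locus with 12 planted NGG sites and its truth table."""
    return generate_fixture_locus(seed=7, length=2000, planted_pams=12)


@pytest.fixture(scope="session")
def planted_site(fixture_locus):
    """One planted plus-strand site of the synthetic locus."""
    record, truth = fixture_locus
    sites = find_cut_sites(record, "NGG")
    wanted = int(truth.pam_start.iloc[0])
    return next(s for s in sites if s.strand == "+" and s.pam_start == wanted)
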