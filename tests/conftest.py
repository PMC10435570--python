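import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from bemux.guide_design import default_registry, registry_by_name
from bemux.seqmodel import Transcript

# First 18 codons of the canonical KRAS reading frame: codon 12 is GGT.
KRAS_CDS = "ATGACTGAATATAAACTTGTGGTAGTTGGAGCTGGTGGCGTAGGCAAGAGTGCC"


@pytest.fixture(scope="session")
def kras():
    return Transcript("KRAS", KRAS_CDS, role="oncogene")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def registry_map():
    return registry_by_name()


def random_transcript(rng: np.random.Generator, n_codons: int = 30) -> Transcript:
    """A fully random (uniform ACGT) transcript with 25-nt flanks."""
    bases = "ACGT"
    pick = lambda k: "".join(bases[i] for i in rng.integers(4, size=k))
    return Transcript(
        "RND", pick(3 * n_codons), up_flank=pick(25), down_flank=pick(25)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
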