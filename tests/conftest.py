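import numpy as np
import pytest

from smrtbs.amplicon import AmpliconReference
from smrtbs.demux import BarcodeManifest, ManifestEntry
from smrtbs.simulate import random_amplicon


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ref():
    # 2 CpGs (positions 2 and 8), non-CpG cytosines on both strands
    return AmpliconReference.from_sequence("amp1", "AACGTACCGTGATCGGTACT")


@pytest.fixture
def manifest():
    return BarcodeManifest([
        ManifestEntry("s1", "ACGTACGTACGTACGTAA", "TTGCATGCATGCATGCAT",
                      "TATCGGTACGAACTGAGG", "CAGTTCGGAGATCGTTCA"),
        ManifestEntry("s2", "GGTTCCAAGGTTCCAAGG", "CCAATTGGCCAATTGGCC",
                      "TATCGGTACGAACTGAGG", "CAGTTCGGAGATCGTTCA"),
    ])


@pytest.fixture
def random_ref(rng):
    return random_amplicon(rng, 300, 12, "rand1")


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
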