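import numpy as np
import pytest

from dscout.germline import GermlineSegment, GermlineSet, packaged_locus_table

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def locus_table() -> GermlineSet:
    return packaged_locus_table()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_d_genes() -> GermlineSet:
    return GermlineSet(
        [
            GermlineSegment("G1", "GTATTACGATTTTTGGAGTGGTTATTAT"),
            GermlineSegment("G2", "AGGATATTGTAGTAGTACCAGCTGCTAT"),
            GermlineSegment("G3", "GTGGATACAGCTATGGTTCGGGGAGTTA"),
        ],
        kind="D",
    )
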