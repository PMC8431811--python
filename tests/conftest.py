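import numpy as np
import pytest

from sscpkit.alignment import Alignment

# the published primer pair this toolkit's thermodynamic screens are
# benchmarked against
FWD_PRIMER = "GCAGTAAATCGGGGCTAATAC"
REV_PRIMER = "CCCGTTACAACCATGGTA"


@pytest.fixture
def tiny_alignment() -> Alignment:
    return Alignment(
        [
            ("s1", "ACG"),
            ("s2", "ACG"),
            ("s3", "ACG"),
            ("s4", "ACT"),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_oligo(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
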