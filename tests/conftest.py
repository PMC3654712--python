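import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# 122-nt ITS1 wild-type amplicon used for the alignment worked examples;
# its GGC at position 61 is the replacement site for the variant sequences.
WILD_TYPE = (
    "AACGAATGGGTCTTCGGGCCCTTCCAACCCTCAAAACCTGTGGAAGCAAAAGATGTGTTTCGGCGCCGCC"
    "GCGCGCCGCATTTATGCAGCGTTATGCTTGTTGTCTGGATTGCAAAGAAATT"
)
GGC_SITE = 61


def replace_ggc(insert: str) -> str:
    """Variant of the wild-type with the GGC site replaced by ``insert``."""
    assert WILD_TYPE[GGC_SITE : GGC_SITE + 3] == "GGC"
    return WILD_TYPE[:GGC_SITE] + insert + WILD_TYPE[GGC_SITE + 3 :]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, length, alphabet="ACGT"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))
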