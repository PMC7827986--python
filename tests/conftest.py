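import pytest

from teaudit import ScoringMatrix
from teaudit.simgen import make_subfamily_library


@pytest.fixture
def unit_matrix():
    """+1 match / -1 mismatch over ACGT."""
    return ScoringMatrix.from_match_mismatch(1, -1)


@pytest.fixture
def tiny_library():
    """Three subfamilies over two types, 4 diagnostic sites per split."""
    return make_subfamily_library(
        ancestral_length=120,
        n_subfamilies=3,
        diagnostic_per_split=4,
        type_partition=["T1", "T1", "T2"],
        seed=11,
        identity=0.9,
    )
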