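import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from genorigin import ScoringScheme

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scoring() -> ScoringScheme:
    """Default BLOSUM62 scoring scheme shared across tests."""
    return ScoringScheme()


@pytest.fixture(scope="session")
def match3_scoring() -> ScoringScheme:
    """Simple +3/-2 match/mismatch scheme with small gap costs.

    Used with a 3-letter alphabet so brute-force alignment enumeration stays
    tractable; X remains neutral at 0.
    """
    mat = np.full((21, 21), -2, dtype=np.int32)
    np.fill_diagonal(mat, 3)
    mat[20, :] = 0
    mat[:, 20] = 0
    return ScoringScheme(matrix=mat, gap_open=5, gap_extend=2)
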