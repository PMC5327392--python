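from __future__ import annotations

import numpy as np
import pytest

from adjmotif import FrequencyMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def random_matrix_factory(rng):
    """Factory for random, strictly positive frequency matrices."""

    def make(length: int, motif_id: str = "RND", alpha: float = 0.5) -> FrequencyMatrix:
        probs = rng.dirichlet([alpha] * 4, size=length).T
        probs = (probs + 1e-6) / (1 + 4e-6)
        return FrequencyMatrix(motif_id=motif_id, probs=probs, pseudocount_applied=True)

    return make


TRANSFAC_TWO_BLOCKS = """\
ID  V$ALPHA_01
BF  T00001 alpha factor
P0      A      C      G      T
01      1      2      1      1
02      0      5      0      0
03      4      0      1      0
//
ID  V$BETA_02
P0      A      C      G      T
01      0.2      0.4      0.2      0.2
02      0.7      0.1      0.1      0.1
//
"""


@pytest.fixture
def transfac_text():
    return TRANSFAC_TWO_BLOCKS
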