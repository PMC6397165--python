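import numpy as np
import pytest

from chromatophore.digest import ProteinRecord


@pytest.fixture
def small_proteome():
    return [
        ProteinRecord("P1", "MKTAYRGSPK", "test protein one"),
        ProteinRecord("P2", "AAAKRRPLLK", "test protein two"),
        ProteinRecord("P3", "GGGGGG", "no cleavage sites"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
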