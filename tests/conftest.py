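import numpy as np
import pytest

from binpu.pu_core import PositiveSet
from binpu.records import CompoundRecord, InteractionPair, ProteinRecord


@pytest.fixture
def tiny_entities():
    """3 compounds x 2 proteins with valid strings."""
    compounds = [
        CompoundRecord("c1", "CCO"),
        CompoundRecord("c2", "c1ccoc1"),
        CompoundRecord("c3", "N#CC(=O)"),
    ]
    proteins = [
        ProteinRecord("p1", "ACDEFGHIKLMNP"),
        ProteinRecord("p2", "MKTAYIAKQRQIS"),
    ]
    return compounds, proteins


@pytest.fixture
def tiny_positives():
    return PositiveSet(
        (InteractionPair("c1", "p1"), InteractionPair("c2", "p2"))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
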