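import numpy as np
import pytest

from barcodegap import SimulationConfig, simulate_community
from barcodegap.seq_io import BarcodeAlignment, BarcodeRecord


@pytest.fixture(scope="session")
def community():
    """Default synthetic community (5 genera x 4 species x 4 individuals)."""
    return simulate_community(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def community_aln(community):
    return community[0]


@pytest.fixture(scope="session")
def community_truth(community):
    return community[1]


@pytest.fixture
def tiny_aln():
    """Two species x two individuals, 12 bp, hand-checkable."""
    recs = [
        BarcodeRecord("a1", "ATGATTGGTACA", species="Aedes albopictus", site="S1"),
        BarcodeRecord("a2", "ATGATTGGTACG", species="Aedes albopictus", site="S2"),
        BarcodeRecord("b1", "ATGCTTGCTACA", species="Aedes vexans", site="S1"),
        BarcodeRecord("b2", "ATGCTTGCTACC", species="Aedes vexans", site="S2"),
    ]
    return BarcodeAlignment(recs, frame_offset=0)
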