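import numpy as np
import pytest

from foundertrace.genmap import GeneticMap
from foundertrace.simulate import make_rflp_fixture


@pytest.fixture(scope="session")
def toy_map() -> GeneticMap:
    """Three knots: (100, 0 cM), (200, 1 cM), (300, 2 cM) on chr1."""
    gmap = GeneticMap()
    gmap.add_chromosome("chr1", [100, 200, 300], [0.0, 1.0, 2.0])
    return gmap


@pytest.fixture(scope="session")
def rflp_fixture():
    """(template, primers, wt amplicon, mut amplicon) for the digestion assay."""
    return make_rflp_fixture()


@pytest.fixture(scope="session")
def identity_map() -> GeneticMap:
    """1 cM/Mb constant-rate map over 100 Mb of chr9."""
    gmap = GeneticMap()
    gmap.add_chromosome("chr9", [1, 100_000_000], [0.0, (100_000_000 - 1) / 1e6])
    return gmap
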