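import pytest

from barcodegap import distance_matrix, fixture_published_dataset, load_printed_barcodes
from barcodegap.simulate import DeletionSpec, SimConfig, simulate_alignment


@pytest.fixture(scope="session")
def printed():
    """The seven published 652 bp barcodes (one record per species)."""
    return load_printed_barcodes()


@pytest.fixture(scope="session")
def printed_matrix(printed):
    return distance_matrix(printed)


@pytest.fixture(scope="session")
def indel_fixture():
    """658-column alignment: seven gapped barcodes + gap-free synthetic reference."""
    return fixture_published_dataset()


@pytest.fixture(scope="session")
def sim_default():
    """Generator defaults, seed 1, with a two-species deletion clade."""
    cfg = SimConfig(seed=1, deletion=DeletionSpec(clade=["sp1", "sp2"]))
    return simulate_alignment(cfg) + (cfg,)
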