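import pytest
from importlib import resources

from aludel import parse_rm_out
from aludel.simulate import SimConfig, simulate_locus


@pytest.fixture(scope="session")
def locus_table():
    """The packaged repeat annotation of the 9358 bp exon 9-11 window."""
    text = (resources.files("aludel.data") / "polh_exon9_11_repeats.out").read_text()
    return parse_rm_out(text)


@pytest.fixture(scope="session")
def default_sim():
    """One default simulated locus, shared read-only across tests."""
    return simulate_locus(SimConfig(seed=42))
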