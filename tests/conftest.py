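import pytest

from tileprobe.genome import CIRCULAR, LINEAR, GenomeMolecule, build_pseudomolecule


@pytest.fixture
def circular10():
    return GenomeMolecule("chr", "ACGTACGTAC", CIRCULAR)


@pytest.fixture
def two_linear():
    return [
        GenomeMolecule("m1", "AAAA", LINEAR),
        GenomeMolecule("m2", "CCCC", LINEAR),
    ]


@pytest.fixture
def pseudo_two_linear(two_linear):
    return build_pseudomolecule(two_linear, 3, spacer_len=3)
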