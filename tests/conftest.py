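import pytest

from tcb1kit.cross_model import PlantGenotype


@pytest.fixture
def tcb1_purple_donor() -> PlantGenotype:
    """Standard maize donor: no barrier genes, purple-siring R1-sc marker."""
    return PlantGenotype.homozygous("tcb1", r1="R1-sc")


@pytest.fixture
def tcb1s_yellow_donor() -> PlantGenotype:
    """Teosinte-haplotype donor: Tcb1-s with the yellow-siring r1 allele."""
    return PlantGenotype.homozygous("Tcb1-s", r1="r1-r")


@pytest.fixture
def neutral_female() -> PlantGenotype:
    return PlantGenotype.homozygous("tcb1")
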