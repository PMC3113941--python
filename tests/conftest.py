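import pytest

from dimersite import Genome, SearchConfig, generate_genome

# the worked-example half-site pair used throughout: a three-finger pair
# targeting the IL2R-gamma locus, 12 nt per half-site
LEFT = "AAAGCGGCTCCG"
RIGHT = "ACTCTGTGGAAG"
IL2RG_TARGET = "CGGAGCCGCTTTAACCCACTCTGTGGAAG"  # revcomp(L) + aaccc + R


@pytest.fixture
def il2rg_cfg() -> SearchConfig:
    return SearchConfig.build(LEFT, RIGHT, "5,6", max_mismatches=0, homodimer=True)


def implant(seq: str, insert: str, pos: int) -> str:
    """Overwrite seq[pos:pos+len(insert)] with insert."""
    assert pos + len(insert) <= len(seq)
    return seq[:pos] + insert + seq[pos + len(insert):]


@pytest.fixture
def random_genome_5kb() -> Genome:
    return generate_genome(5_000, seed=42)
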