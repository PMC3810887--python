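import pytest

from msatpal.pal_stats import SpeciesTally
from msatpal.synthetic_reads import SimConfig, SpeciesSim


@pytest.fixture
def published_tallies():
    """The three-species newt run: printed read/candidate/NTPP/SIPL counts."""
    return [
        SpeciesTally("T. cristatus", 19562, 936, 107, ntpp=41, sipl=11),
        SpeciesTally("C. asper", 52075, 1083, 316, ntpp=41, sipl=20),
        SpeciesTally("L. helveticus", 55626, 1434, 319, ntpp=22, sipl=15),
    ]


def small_sim_config(seed=0, n_reads=100, **kwargs) -> SimConfig:
    """A scaled-down simulation config for fast tests."""
    base = SimConfig()
    species = tuple(
        SpeciesSim(sp.label, sp.tags, n_reads) for sp in base.species
    )
    return SimConfig(seed=seed, species=species, **kwargs)
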