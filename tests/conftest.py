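import pytest

from mmseq.core.umi import default_pool
from mmseq.simulate import ContigSpec, SimConfig, simulate_library


@pytest.fixture(scope="session")
def pool():
    return default_pool()


@pytest.fixture(scope="session")
def noise_free_sim(pool):
    """A small library with every noise parameter at its clean limit."""
    cfg = SimConfig(
        contigs={"chr1": ContigSpec(5_000, n_molecules=300)},
        conversion_sensitivity=1.0, conversion_specificity=1.0,
        analog_resistance=1.0, strand_survival=1.0, pcr_duplicate_rate=0.0,
        seed=11)
    return simulate_library(cfg, pool)
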