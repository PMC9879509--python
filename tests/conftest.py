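import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from tandemscope.synthetic_data import SimulationConfig, generate_genome


@pytest.fixture(scope="session")
def sim():
    """A mid-size synthetic genome with planted genic and intergenic TRs."""
    cfg = SimulationConfig(
        genome_length=60_000, n_genic_trs=6, n_intergenic_trs=6,
        n_orfs=16, partial_flank_prob=0.7, seed=11,
    )
    genome, orfs, truth = generate_genome(cfg)
    return genome, orfs, truth


@pytest.fixture(scope="session")
def sim_cfg(sim):
    return sim[2].config
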