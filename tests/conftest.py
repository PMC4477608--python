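import numpy as np
import pytest

from breedscan import synthdata


@pytest.fixture(scope="session")
def ideal_world():
    """Noise-free world: breeds exactly fixed for their phenotype haplotype,
    no read error — every planted signal is deterministic."""
    cfg = synthdata.SimConfig(seed=11, n_snps=200, error_rate=0.0,
                              drift_strength=np.inf, recomb_rate=0.0)
    panel = synthdata.simulate_breed_panel(cfg)
    truth = synthdata.simulate_haplotype_pools(cfg, panel)
    pools = synthdata.simulate_pool_pileups(truth, cfg)
    return cfg, panel, truth, pools


@pytest.fixture(scope="session")
def drifted_world():
    """Realistic world with breed drift and read error."""
    cfg = synthdata.SimConfig(seed=23, n_snps=120)
    panel = synthdata.simulate_breed_panel(cfg)
    truth = synthdata.simulate_haplotype_pools(cfg, panel)
    pools = synthdata.simulate_pool_pileups(truth, cfg)
    return cfg, panel, truth, pools
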