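import numpy as np
import pytest

import landracegp as lg


@pytest.fixture(scope="session")
def gmap_small():
    """Two 100-cM chromosomes, 150 markers each, 100 Mb (1 cM/Mb)."""
    return lg.make_genetic_map(2, 150, 100.0, 100e6, seed=11)


@pytest.fixture(scope="session")
def pool_hwe(gmap_small):
    """Large burnin-free pool: independent loci, exact HWE reference."""
    return lg.simulate_ancestral_pool(gmap_small, 4000, burnin_generations=0, seed=12)


@pytest.fixture(scope="session")
def landrace(gmap_small):
    """Drifted pool with LD plus its capture line (3% private loci)."""
    pool = lg.simulate_ancestral_pool(gmap_small, 400, burnin_generations=12, seed=13)
    capture, pool = lg.make_capture_line(pool, private_fraction=0.03, seed=14)
    return pool, capture


def make_fixed_p_pool(p, n_markers, pool_size, seed):
    """Pool with every locus at the same ancestral frequency, no linkage."""
    gmap = lg.make_genetic_map(1, n_markers, 100.0, 100e6, seed=seed)
    rng = np.random.default_rng(seed)
    gametes = (rng.random((pool_size, n_markers)) < p).astype(np.uint8)
    return lg.GametePool(gametes=gametes, gmap=gmap)
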