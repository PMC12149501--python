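import numpy as np
import pytest

from preselsim import genome as gn
from preselsim import traits as tr


@pytest.fixture(scope="session")
def mini_map():
    rng = np.random.default_rng(11)
    return gn.random_genome_map([80.0, 60.0], 400, rng)


@pytest.fixture(scope="session")
def mini_pool(mini_map):
    """Small equilibrium pool: 60 individuals, 40 neutral generations."""
    return gn.simulate_founder_pool(mini_map, 60, 40, 2.5e-8, 123)


@pytest.fixture(scope="session")
def mini_setup(mini_pool):
    """Founders -> panels -> base population -> calibrated QTL effects."""
    founders = gn.expand_founders(mini_pool, 10, 10, 2, 10, 7)
    panel_map = gn.select_locus_panels(founders, 0.05, 150, 30, 8)
    base, gmap = gn.make_base_population(founders, panel_map, 12, 48, 9)
    params = tr.TraitParams()
    v_g, _ = tr.build_covariance_matrices(params)
    effects = tr.calibrate_qtl_effects(base.allele_counts(gmap.qtl_idx), v_g, 10)
    return {"base": base, "gmap": gmap, "params": params, "effects": effects}


def random_pedigree(n_founders: int, n_offspring: int, seed: int):
    """Topologically ordered random pedigree with sexed parents."""
    rng = np.random.default_rng(seed)
    n = n_founders + n_offspring
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    sex = rng.random(n) < 0.5
    sex[0], sex[1] = True, False        # guarantee one of each
    for i in range(n_founders, n):
        males = np.flatnonzero(sex[:i])
        females = np.flatnonzero(~sex[:i])
        sire[i] = rng.choice(males)
        dam[i] = rng.choice(females)
    return sire, dam, sex
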