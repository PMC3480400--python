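import numpy as np
import pytest

from divgrid import GenotypeTable
from divgrid.simulate import SimConfig, simulate_frequencies, simulate_individuals


@pytest.fixture
def tiny_table():
    """Six individuals, three loci, with one heterozygote and one missing pair."""
    calls = np.array([
        [[152, 158], [200, 200], [101, 103]],
        [[152, 152], [200, 204], [101, 101]],
        [[158, 158], [204, 204], [103, 103]],
        [[152, 158], [200, 204], [-1, -1]],
        [[152, 152], [200, 200], [101, 103]],
        [[158, 158], [200, 204], [103, 105]],
    ])
    return GenotypeTable([f"i{k}" for k in range(6)], ["L1", "L2", "L3"], calls)


def small_dataset(k_pops=3, n_loci=20, n_per_pop=30, seed=9, centers=None,
                  missing_rate=0.0, **kw):
    """A compact synthetic dataset with truth, for structural tests."""
    if centers is None:
        centers = [(-70.0, -5.0), (-60.0, -5.0), (-65.0, 0.0)][:k_pops]
    cfg = SimConfig(k_pops=k_pops, n_loci=n_loci, n_per_pop=n_per_pop,
                    centers=centers, missing_rate=missing_rate, seed=seed, **kw)
    rng = np.random.default_rng(seed)
    freqs, _ = simulate_frequencies(cfg, rng)
    gt, pp, truth = simulate_individuals(freqs, cfg, rng)
    return gt, pp, truth, cfg


@pytest.fixture(scope="session")
def small_scenario():
    return small_dataset()
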