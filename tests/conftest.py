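import pytest

from cncnet.simulate import SimConfig, simulate_all

#: fixed seed list for the standard planted-truth fixture
STANDARD_SEEDS = (101, 211, 307)

#: downsized configuration for fast end-to-end pipeline tests
SMALL_SIM = dict(n_mrna=400, n_lncrna=60, n_circrna=30, frac_de=0.2,
                 n_coexpr_pairs=6, n_terms=12, module_size=12)


@pytest.fixture(scope="session")
def std_bundle():
    """Full-size standard fixture at the first standard seed."""
    return simulate_all(SimConfig(seed=STANDARD_SEEDS[0]))


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_all(SimConfig(seed=5, **SMALL_SIM))
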