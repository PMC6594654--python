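import pytest

import f1loh as f


@pytest.fixture(scope="session")
def m73():
    """One simulated 73m-like trio (duplicated driver, resistant subclone)."""
    config = f.preset_config("73m-like")
    return config, f.simulate_pair(config)


@pytest.fixture(scope="session")
def jw81():
    """One simulated jw81-like trio (de novo resistance mutation)."""
    config = f.preset_config("jw81-like")
    return config, f.simulate_pair(config)


@pytest.fixture(scope="session")
def flat_sim():
    """A trio with no events and no mutations: everything retained-het."""
    config = f.SimConfig(seed=5, n_chromosomes=3, chrom_length_bp=50_000_000,
                         snp_density=1.0, mean_depth_normal=100.0,
                         mean_depth_tumor=100.0, purity_primary=0.9,
                         purity_relapse=0.9)
    return config, f.simulate_pair(config)
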