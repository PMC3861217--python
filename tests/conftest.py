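import numpy as np
import pytest

from symbiovar.synthgen import SimConfig, generate_dataset


def small_config(**overrides) -> SimConfig:
    """Desk-scale study configuration: 100 kb genome, 40 genes, 21 kb cassette."""
    defaults = dict(
        seed=1,
        fixed_diff_composition=(6, 4, 5),
        n_fixed_diffs=15,
        private_snp_rate=1e-5,
        ambiguous_rate=1e-5,
        n_indels=3,
        carrier_unique_snps=2,
        carrier_ambiguous_sites=6,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def dataset():
    """One full synthetic dataset shared across read-only tests."""
    return generate_dataset(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
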