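"""Shared fixtures: small synthetic landscapes reused across test modules.

The small landscape (2,000 reference peaks) keeps per-module tests fast;
full-size fixtures are built only where a check is defined at n = 10,000.
"""

import numpy as np
import pytest

from relascape.simulate import SyntheticConfig, build_landscape


def small_config(**overrides) -> SyntheticConfig:
    base = dict(
        n_ref_peaks=2_000,
        n_partner_specific=500,
        se_cluster_count=5,
        se_cluster_size=20,
        n_up_genes=80,
        n_down_genes=32,
        n_constitutive_genes=200,
        n_variant_peaks=50,
        sharing_counts=(100, 200, 300, 100),
        generate_sequences=False,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_landscape():
    return build_landscape(small_config(), seed=1234)


@pytest.fixture(scope="session")
def small_null_landscape():
    return build_landscape(small_config().null_variant(), seed=1234)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
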