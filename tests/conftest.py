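import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from cladecompare import CladeConfig, DECountsConfig, generate_clade, generate_counts


@pytest.fixture(scope="session")
def small_clade():
    """A 3-vs-4 clade: quick enough for per-module tests."""
    return generate_clade(
        CladeConfig(
            n_group_a=3, n_group_b=4, n_core_families=8,
            n_exclusive_gains=2, n_exclusive_losses=1,
            n_diagnostic_families=2, mean_protein_length=100,
            background_divergence=0.05, seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_counts(small_clade):
    return generate_counts(
        small_clade,
        DECountsConfig(n_de=4, log2fc_magnitude=1.5, dispersion=0.1,
                       mean_expression=400.0, seed=12),
    )
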