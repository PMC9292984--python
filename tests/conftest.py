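import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from madstargets import SyntheticConfig, generate_bundle


def small_config(seed: int = 3) -> SyntheticConfig:
    """A scaled-down generator configuration for fast unit tests."""
    return SyntheticConfig(
        seed=seed,
        n_genes=120,
        n_chrom=2,
        chrom_length_bp=600_000,
        n_true_targets=25,
        n_background_peaks=60,
    )


@pytest.fixture(scope="session")
def small_bundle():
    return generate_bundle(small_config())


@pytest.fixture(scope="session")
def default_bundle():
    """The benchmark-scale bundle (4 complexes, 50 targets, 200 background
    peaks, 3 replicates) used by the end-to-end recovery tests."""
    return generate_bundle(SyntheticConfig(seed=11))
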