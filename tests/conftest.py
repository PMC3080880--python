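import pytest

from anchorlign.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def small_truth():
    """A small simulated dataset without artifacts (shared, read-only)."""
    return simulate(SimConfig(n_taxa=12, n_queries=3, seed=11,
                              artifact_fractions=(0.0, 0.0, 0.0)))


@pytest.fixture(scope="session")
def default_truth():
    """One dataset under the package's standard study conditions."""
    return simulate(SimConfig(seed=7))
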