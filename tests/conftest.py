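import pytest

from chemconsensus import (
    EXAMPLE_FIXTURE_DIR,
    WorldSpec,
    build_world,
    load_fixture_world,
)


@pytest.fixture(scope="session")
def example_registry():
    """The packaged two-source apomorphine worked-example world."""
    return load_fixture_world(EXAMPLE_FIXTURE_DIR)


@pytest.fixture(scope="session")
def clean_world():
    """Small generated world with zero corruption (ground truth recoverable)."""
    return build_world(WorldSpec(n_compounds=25, corruption_prob=0.0, seed=42))


@pytest.fixture(scope="session")
def noisy_world():
    """Generated world with per-source corruption, for end-to-end checks."""
    return build_world(WorldSpec(n_compounds=40, corruption_prob=0.25, seed=7))
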