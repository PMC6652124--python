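import pandas as pd
import pytest

from gapmap.synthetic_data import SyntheticConfig, generate_world, worked_fixture


@pytest.fixture(scope="session")
def fixture_data() -> dict:
    """Tiny hand-checkable dataset with frozen expected outputs."""
    return worked_fixture()


@pytest.fixture(scope="session")
def small_world() -> tuple[pd.DataFrame, pd.DataFrame, SyntheticConfig]:
    """A small synthetic world (10 states, ~200 raw records) shared across
    read-only tests."""
    config = SyntheticConfig(rng_seed=42)
    counties, resources = generate_world(config)
    return counties, resources, config
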