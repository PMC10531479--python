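import pytest

from fdtox import GeneratorConfig, generate_dataset

# compact study-shaped dataset reused across the suite: same grammar and
# response structure as the defaults, scaled down for speed
SMALL = GeneratorConfig(n_compounds=60, n_train=45, seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(SMALL)


@pytest.fixture(scope="session")
def default_dataset():
    """Full study-sized table (169 compounds, 127 train)."""
    return generate_dataset(GeneratorConfig(seed=7))
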