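import pytest

from sonosym import SyntheticConfig, default_table, generate_corpus


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def default_corpus():
    """One default-condition synthetic corpus shared across tests."""
    records, truth = generate_corpus(SyntheticConfig(seed=11))
    return records, truth


@pytest.fixture(scope="session")
def separable_corpus():
    """Deterministic movement→manner code, no speaker noise."""
    cfg = SyntheticConfig(beta_manner=1.0, beta_vowel=1.0, sigma_speaker=0.0, seed=13)
    records, truth = generate_corpus(cfg)
    return records, truth


@pytest.fixture(scope="session")
def null_corpus():
    """No planted structure at all."""
    cfg = SyntheticConfig(beta_manner=0.0, beta_vowel=0.0, seed=17)
    records, truth = generate_corpus(cfg)
    return records, truth
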