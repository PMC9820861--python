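import pytest

from nbgcloner import synthetic_data as sd


@pytest.fixture(scope="session")
def planted_study(tmp_path_factory):
    """One full synthetic study with a planted causal gene, shared across
    tests that only read it."""
    out = tmp_path_factory.mktemp("study")
    paths, truth = sd.generate_study(out, seed=11)
    return paths, truth


@pytest.fixture(scope="session")
def null_study(tmp_path_factory):
    out = tmp_path_factory.mktemp("null_study")
    paths, truth = sd.generate_study(out, seed=11, planted=False)
    return paths, truth
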