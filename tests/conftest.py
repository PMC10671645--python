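import pytest

from permpbpk import load_physiology, make_toy_body


@pytest.fixture(scope="session")
def phys():
    """The packaged 70 kg / 300 L/h reference physiology."""
    return load_physiology()


@pytest.fixture(scope="session")
def toy():
    """A small balanced body (liver + lung + gut + 2 generic tissues)."""
    return make_toy_body(2, seed=7)
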