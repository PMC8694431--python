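import pytest

from cylcap import build_surrogate_surface, make_powerlaw_surface, make_table3_fixtures


@pytest.fixture(scope="session")
def surrogate_surface():
    """Default stitched surrogate surface (51 x 40 grid)."""
    return build_surrogate_surface()


@pytest.fixture(scope="session")
def empirical_surface():
    """Pure power-law surface with the empirical rigid-cylinder exponents."""
    return make_powerlaw_surface(0.718, 2.08, 0.224)


@pytest.fixture(scope="session")
def table3_configs():
    return make_table3_fixtures()
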