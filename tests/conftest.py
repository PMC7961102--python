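import pytest

from cofilsev import synthetic_data as syn


@pytest.fixture(scope="session")
def bare18():
    """Noise-free ideal bare-actin-like filament, 18 subunits at 167 deg."""
    return syn.make_bare_filament(18, seed=0)


@pytest.fixture(scope="session")
def bare10():
    return syn.make_bare_filament(10, seed=0)


@pytest.fixture(scope="session")
def cofilactin11():
    """Periodic fully decorated cofilactin: 11 subunits, 10 cofilins."""
    return syn.make_cofilactin_filament(11, seed=0)


@pytest.fixture(scope="session")
def cofilactin12():
    return syn.make_cofilactin_filament(12, seed=0)


@pytest.fixture(scope="session")
def slow_model(bare10, cofilactin12):
    from cofilsev.boundary_builder import splice_boundary

    return splice_boundary(bare10, cofilactin12, "slow")


@pytest.fixture(scope="session")
def fast_model(bare10, cofilactin12):
    from cofilsev.boundary_builder import splice_boundary

    return splice_boundary(bare10, cofilactin12, "fast")
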