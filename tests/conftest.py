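import pytest

import amplitrait as at


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study at the generator's default seed."""
    return at.simulate_study(seed=0)


@pytest.fixture(scope="session")
def rarefied(bundle):
    table, _ = at.rarefy(bundle.counts, depth=2000, seed=0)
    return table


@pytest.fixture(scope="session")
def metadata(bundle, rarefied):
    return bundle.metadata.loc[rarefied.index]


@pytest.fixture(scope="session")
def assignments(bundle):
    return at.assign_traits(bundle.otus, bundle.reference)


@pytest.fixture(scope="session")
def profiles(rarefied, assignments):
    return at.community_weighted_traits(rarefied, assignments)
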