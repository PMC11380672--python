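import numpy as np
import pytest
from hypothesis import settings

import commselect as cs

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def pool():
    return cs.default_pool()


@pytest.fixture(scope="session")
def cmap():
    return cs.default_compatibility()


@pytest.fixture(scope="session")
def empty_cmap():
    return cs.CompatibilityMap()


@pytest.fixture(scope="session")
def paper11():
    return cs.make_fixture("paper11")


@pytest.fixture(scope="session")
def paper11_quiet(paper11):
    return paper11.noise_free()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240907)


def random_offspring(pool, cmap, rng, n=29, k=4, round_index=1):
    """Uniform draw of n legal k-communities, as a plain offspring list."""
    allowed = cs.enumerate_allowed(pool, cmap, k)
    return [
        cs.Community(
            members=allowed[int(rng.integers(len(allowed)))],
            community_id=f"r{round_index}-s{i:02d}",
            round_index=round_index,
            treatment="selection",
        )
        for i in range(n)
    ]
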