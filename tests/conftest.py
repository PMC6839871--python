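import numpy as np
import pytest
from hypothesis import settings

from pollinet import GeneratorConfig, SpeciesRecord, SiteCommunity, generate_site

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


def make_community(counts, origins=None, flower_counts=None, site_id="demo"):
    counts = np.asarray(counts, dtype=float)
    r, c = counts.shape
    origins = origins or ["native"] * r
    flower_counts = flower_counts or [10] * r
    plants = [
        SpeciesRecord(species_id=f"p{i}", guild="plant", origin=origins[i],
                      flower_count=flower_counts[i])
        for i in range(r)
    ]
    visitors = [SpeciesRecord(species_id=f"v{j}", guild="visitor") for j in range(c)]
    return SiteCommunity(site_id=site_id, plants=plants, visitors=visitors, counts=counts)


@pytest.fixture
def demo_community():
    """3 plants (one alien) x 3 visitors, every species interacting."""
    return make_community(
        [[3, 1, 0], [1, 1, 1], [0, 2, 1]],
        origins=["native", "native", "alien"],
        flower_counts=[10, 20, 5],
    )


@pytest.fixture(scope="session")
def synthetic_site():
    """One default-configuration synthetic site plus its trait table."""
    return generate_site(GeneratorConfig(seed=1), 0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
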