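import pytest
from hypothesis import HealthCheck, settings

import potlipid as pl
from potlipid import simulate as sim

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def refs():
    return pl.load_reference_classes()


@pytest.fixture(scope="session")
def specs(refs):
    return sim.default_specs(refs)


@pytest.fixture(scope="session")
def noisy_assemblage(refs, specs):
    """A modest seeded assemblage reused by aggregation and io tests."""
    spec = sim.default_assemblage_spec()
    records, truths = sim.generate_assemblage(
        spec, n=120, seed=11, specs=specs, refs=refs
    )
    return records, truths


@pytest.fixture(scope="session")
def noisy_profiles(noisy_assemblage, refs):
    records, _ = noisy_assemblage
    return [(r, pl.build_commodity_profile(r, refs)) for r in records]
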