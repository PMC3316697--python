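import pytest
from hypothesis import HealthCheck, settings

from sympatria import AquiferCensus, SisterTally

settings.register_profile(
    "default",
    derandomize=True,
    database=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def yilgarn_census() -> AquiferCensus:
    """The in-study census: 18/16/11 aquifers with 1/2/3 species, 45 total."""
    return AquiferCensus.from_counts(18, 16, 11)


@pytest.fixture(scope="session")
def observed_tally(yilgarn_census) -> SisterTally:
    """The observed 9 sister pairs and 2 triplets out of 45 aquifers."""
    return SisterTally(pair_aquifers=9, triplet_aquifers=2, total_aquifers=45)
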