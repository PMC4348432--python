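import pytest

from micekit.cohort import load_fixture, load_study_observations
from micekit.theory import level_bits, theoretical_profile


@pytest.fixture(scope="session")
def records():
    return load_fixture()


@pytest.fixture(scope="session")
def by_id(records):
    return {r.id: r for r in records}


@pytest.fixture(scope="session")
def profiles(records):
    """Theoretical feature counts for the whole cohort (computed once)."""
    return {r.id: theoretical_profile(r) for r in records}


@pytest.fixture(scope="session")
def bits(profiles):
    return {rid: level_bits(p) for rid, p in profiles.items()}


@pytest.fixture(scope="session")
def curated_observations(records):
    return load_study_observations(records)
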