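import pytest

from sagame import generate_bank, make_aoi_tracks, simulate_cohort


@pytest.fixture(scope="session")
def bank():
    return generate_bank(seed=7)


@pytest.fixture(scope="session")
def tracks(bank):
    return make_aoi_tracks(bank, seed=7)


@pytest.fixture(scope="session")
def small_cohort(bank, tracks):
    """A small mixed cohort with gaze and counting-span data."""
    return simulate_cohort(8, 6, bank, seed=11, aoi_tracks=tracks)
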