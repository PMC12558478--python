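import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from facdamage.synthetic import CityParams, ErrorParams, generate_city

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


SMALL_CITY = CityParams(
    n_buildings=150,
    bounds=(0.0, 0.0, 1200.0, 1200.0),
    decay_scale_m=350.0,
    n_hospitals=4,
    n_dialysis=2,
    n_pharmacies=40,
)


@pytest.fixture(scope="session")
def small_city():
    """A 150-building city with the default (realistic) error modes."""
    return generate_city(SMALL_CITY, ErrorParams(), seed=11)


@pytest.fixture(scope="session")
def clean_city():
    """A 150-building city with every error mode switched off."""
    return generate_city(SMALL_CITY, ErrorParams.none(), seed=11)
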