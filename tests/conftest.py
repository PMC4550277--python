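import numpy as np
import pytest

from eggshed import synthetic_data as sd


@pytest.fixture(scope="session")
def small_db():
    """Six-species COI database with one planted sister pair (5 diagnostic sites)."""
    params = sd.SeqSimParams(n_species=6, sister_pairs=1, diagnostic_sites_per_pair=5, seed=11)
    return sd.gen_reference_db(params)


@pytest.fixture(scope="session")
def uniform_field():
    """10 km x 10 km grid, 96 hourly maps, constant eastward 10 cm/s."""
    return sd.gen_current_field(
        sd.FieldSimParams(nx=20, ny=20, dx=500.0, n_hours=96, regime="uniform", u0=10.0, seed=0)
    )


@pytest.fixture(scope="session")
def gyre_field():
    return sd.gen_current_field(
        sd.FieldSimParams(nx=21, ny=21, dx=500.0, n_hours=96, regime="gyre", u0=10.0, seed=0)
    )


@pytest.fixture(scope="session")
def collection_events():
    """Default two-year synthetic collection series (266 collections)."""
    return sd.gen_collections(sd.CollectionSimParams(seed=5))
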