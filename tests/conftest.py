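import numpy as np
import pytest

from invasim import (
    MTEConstants,
    Origin,
    Species,
    TraitSet,
    build_island,
    default_architecture,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def island5():
    return build_island(side=5, base_temperature=15.0, precip_range=(0.0, 10.0))


@pytest.fixture
def island3():
    return build_island(side=3, base_temperature=20.0, precip_range=(0.0, 10.0))


@pytest.fixture
def mte():
    return MTEConstants()


def make_species(species_id="S0", origin=Origin.NATIVE_POOL, **overrides) -> Species:
    """A mid-sized, well-adapted test species with overridable mean traits."""
    traits = dict(
        temp_optimum=20.0,
        temp_tolerance=3.0,
        precip_optimum=5.0,
        precip_tolerance=3.0,
        seed_mass=20.0,
        adult_mass=1000.0,
        dispersal_scale=0.5,
        dispersal_shape=2.0,
    )
    traits.update(overrides)
    return Species(
        species_id=species_id,
        mean_traits=TraitSet(**traits),
        origin=origin,
        architecture=default_architecture(),
    )
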