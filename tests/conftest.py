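import numpy as np
import pytest

from shgdir.mc import build_lookup_table
from shgdir.optics import DetectionGeometry, MCConfig, OpticalProperties


@pytest.fixture(scope="session")
def geometry():
    return DetectionGeometry()


@pytest.fixture(scope="session")
def optics_scatter():
    """Collagenous-tissue-like slab: mu_s'=2/mm, g=0.9, n=1.4, 150 um."""
    return OpticalProperties(
        mu_s_reduced=2.0, anisotropy_g=0.9, refractive_index=1.4, thickness=150.0
    )


@pytest.fixture(scope="session")
def optics_ballistic():
    return OpticalProperties(
        mu_s_reduced=0.0, anisotropy_g=0.9, refractive_index=1.4, thickness=150.0
    )


@pytest.fixture(scope="session")
def lut_scatter(optics_scatter, geometry):
    """Reduced-scale lookup table shared across tests.

    Full 64-ratio grid, 20 depth rows covering the synthetic stacks,
    1e4 photons per condition.
    """
    config = MCConfig(
        photons_per_condition=10_000,
        rng_seed=7,
        depth_grid=tuple(np.linspace(0.0, 80.0, 20)),
    )
    return build_lookup_table(optics_scatter, geometry, config)


@pytest.fixture(scope="session")
def lut_scatter_alt(optics_scatter, geometry):
    """Independently seeded replicate of ``lut_scatter``.

    Round-trip tests render synthetic stacks through this table and
    invert through ``lut_scatter``, so the two sides carry independent
    Monte Carlo noise.
    """
    config = MCConfig(
        photons_per_condition=10_000,
        rng_seed=8,
        depth_grid=tuple(np.linspace(0.0, 80.0, 20)),
    )
    return build_lookup_table(optics_scatter, geometry, config)


@pytest.fixture(scope="session")
def lut_ballistic(optics_ballistic, geometry):
    """Non-scattering lookup table: measured F/B equals the creation ratio."""
    config = MCConfig(
        photons_per_condition=10_000,
        rng_seed=11,
        depth_grid=tuple(np.linspace(0.0, 80.0, 5)),
    )
    return build_lookup_table(optics_ballistic, geometry, config)
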