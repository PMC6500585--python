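import dataclasses

import numpy as np
import pytest

from nucsize import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom_config():
    """Well-separated plant nuclei, noise-free, z oversampled for accuracy.

    Axial radii of the default oblate nuclei are ~1.3-2 μm, so a 0.4 μm
    z-step keeps the minimum radius above ~3 voxels and rasterization error
    small; lateral sampling is the usual ~0.37 μm.
    """
    return PhantomConfig(shape=(60, 256, 256), dz=0.4, n_plant=10,
                         min_separation_um=12.0, seed=11).noise_free()


@pytest.fixture(scope="session")
def clean_phantom(clean_phantom_config):
    return generate_phantom(clean_phantom_config)


@pytest.fixture(scope="session")
def mixed_phantom():
    """Plant nuclei plus fungal nuclei and wall artifacts, noise-free."""
    cfg = PhantomConfig(shape=(60, 256, 256), dz=0.4, n_plant=8, n_fungal=5,
                        n_wall=3, min_separation_um=13.0, seed=21).noise_free()
    return generate_phantom(cfg), cfg


@pytest.fixture(scope="session")
def spherical_phantom():
    """Noise-free spheres (no flattening), large enough for slab-sum volumes."""
    cfg = dataclasses.replace(
        PhantomConfig(shape=(72, 256, 256), dz=0.5, n_plant=8,
                      min_separation_um=14.0, seed=31).noise_free(),
        flattening=1.0, lateral_jitter=0.0,
        plant_volume_components=(120.0, 160.0), plant_volume_weights=(0.5, 0.5),
        plant_volume_sigma=0.08)
    return generate_phantom(cfg), cfg
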