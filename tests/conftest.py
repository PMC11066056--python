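import numpy as np
import pytest
from hypothesis import settings

import zombiescope as z

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scene():
    """Noise-free, well-separated scene with every object class."""
    spec = z.scene_for_fractions(
        n_cells=40, infected_frac=0.25, zombie_frac=0.1, sar11_frac=0.6,
        n_free_phage=5, dividing_fraction=0.15, seed=7,
        field_shape=(420, 420), noise_sd=0.0,
    )
    field, truth = z.render_field(spec)
    return spec, field, truth


@pytest.fixture(scope="session")
def gates(small_scene):
    spec, _, _ = small_scene
    return z.calibrate_gates(spec)


@pytest.fixture(scope="session")
def noisy_scene():
    spec = z.scene_for_fractions(
        n_cells=60, infected_frac=0.2, zombie_frac=0.1, sar11_frac=0.6,
        n_free_phage=6, dividing_fraction=0.1, seed=3, field_shape=(460, 460),
    )
    field, truth = z.render_field(spec)
    return spec, field, truth
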