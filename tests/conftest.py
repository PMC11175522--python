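import numpy as np
import pytest

from ctaspects import (
    PhantomSpec,
    Region,
    TabularSimSpec,
    Volume3D,
    make_block_atlas,
)


@pytest.fixture(scope="session")
def block_atlas():
    return make_block_atlas()


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-patient tabular cohort with the default class distributions."""
    from ctaspects import simulate_tabular

    return simulate_tabular(TabularSimSpec(n_patients=200, seed=11))


@pytest.fixture
def cube_mask():
    """A 20^3 cube mask centred in a 40^3 1 mm grid."""
    data = np.zeros((40, 40, 40), dtype=np.uint8)
    data[10:30, 10:30, 10:30] = 1
    return Volume3D(data, np.eye(4))


def planted_phantom_spec(**overrides):
    """Zero-noise phantom with hypo-attenuation in M1 and lesions in M1/M2."""
    base = dict(
        noise_sd=0.0,
        rhu_multipliers={Region.M1: 0.85, Region.INSULAR_CORTEX: 0.92},
        lesion_fractions={Region.M1: 0.50, Region.M2: 0.35},
        seed=0,
    )
    base.update(overrides)
    return PhantomSpec(**base)
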