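import numpy as np
import pytest

from rehodyn import BoldSeries, default_affine
from rehodyn.synthetic import CohortConfig, Region


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_bold(rng):
    """Random 10x10x9 series, 60 volumes at TR 2 s."""
    shape = (10, 10, 9, 60)
    return BoldSeries(rng.standard_normal(shape), default_affine(shape[:3], 3.0), 2.0)


@pytest.fixture
def tiny_config():
    """Desk-scale config trimmed further for unit tests."""
    return CohortConfig(
        n_patients=3,
        n_controls=3,
        grid_shape=(12, 12, 9),
        n_volumes=120,
        effect_regions=(Region("up", "reho_up", (6, 6, 4), (2, 2, 1), 0.2),),
        clinical_effects=(),
        seed=11,
    )
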