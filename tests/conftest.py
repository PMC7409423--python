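import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from zfxquant import SimulationParams

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fast_params():
    """Scaled-down larva for quick unit tests: 256x256 px at 1 µm/px.

    Proportions (cells per unit area, debris size ratio, autofluorescence
    contrast) track the full-size defaults; only the field and counts shrink.
    """
    return SimulationParams(
        image_shape=(256, 256),
        pixel_size_um=1.0,
        n_cells=40,
        cell_radius_um=(4.5, 0.3),
        cell_intensity=(10000.0, 1000.0),
        dispersion_sigma_um=45.0,
        trunk_fraction=0.1,
        n_debris=8,
        debris_radius_um=1.0,
        yolk_autofluor_level=300.0,
        noise_sd=50.0,
        seed=7,
        dialect="custom",
    )
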