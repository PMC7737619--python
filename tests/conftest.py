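"""Shared fixtures: small synthetic stacks and sheets built once."""

import numpy as np
import pytest

from zpfilament.helix import HelicalSymmetry
from zpfilament.synthetic import (
    default_filament_model,
    project_segments,
    render_filament_volume,
)


@pytest.fixture(scope="session")
def umod_model():
    return default_filament_model(HelicalSymmetry(62.5, 180.0))


@pytest.fixture(scope="session")
def small_volume(umod_model):
    """64³ voxel rendering of the branch-decorated filament, 6.25 Å/voxel."""
    return render_filament_volume(umod_model, 6.25, 400.0)


@pytest.fixture(scope="session")
def noiseless_stack(small_volume):
    """Eight noiseless projections at evenly spaced view angles."""
    angles = np.arange(8) * 45.0
    return project_segments(small_volume, 6.25, 8, angles,
                            np.zeros(8), 0.0, 0)


@pytest.fixture(scope="session")
def noisy_stack(small_volume):
    """Forty noisy segments (SNR 0.5) with random views and offsets."""
    rng = np.random.default_rng(42)
    n = 40
    angles = rng.uniform(0, 360, n)
    offsets = rng.uniform(-31.25, 31.25, n)
    clean = project_segments(small_volume, 6.25, n, angles, offsets, 0.0, 0)
    noise = float(clean.images.std()) / 0.5
    return project_segments(small_volume, 6.25, n, angles, offsets,
                            noise, 42)
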