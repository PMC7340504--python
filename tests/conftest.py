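import numpy as np
import pytest

from burstfish.synthetic import SceneSpec, render_stack


@pytest.fixture(scope="session")
def standard_scene():
    """A mid-size ground-truthed scene with spots, sites and nuclei."""
    spec = SceneSpec(shape=(20, 512, 512), n_mature_spots=300,
                     n_transcription_sites=12, n_nuclei=30,
                     nucleus_radius=16.0,
                     site_multiplier_range=(4.0, 8.0), seed=11)
    fish, nuclear, truth = render_stack(spec)
    return spec, fish, nuclear, truth


@pytest.fixture(scope="session")
def cutoff_grid():
    return np.arange(120.0, 360.0, 10.0)
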