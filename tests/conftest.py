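import numpy as np
import pytest

from strainquant import SyntheticScene, render_sequence


#: geometry shared by all rendered-scene tests: 3x3 grid, 80 px spacing,
#: 5 px dots, 30 fps for 10 s at 1 Hz, pixel noise sigma 0.02
STUDY_KWARGS = dict(
    grid_shape=(3, 3),
    grid_spacing=80.0,
    dot_radius=5.0,
    frequency=1.0,
    fps=30.0,
    duration=10.0,
    noise_sigma=0.02,
    seed=42,
)


def study_scene(**overrides) -> SyntheticScene:
    kwargs = {**STUDY_KWARGS, **overrides}
    return SyntheticScene(**kwargs)


@pytest.fixture(scope="session")
def rendered_004():
    """One full rendered equibiaxial scene at 4% strain (reused widely)."""
    scene = study_scene(amp_xx=0.04, amp_yy=0.04)
    seq, truth = render_sequence(scene)
    return scene, seq, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
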