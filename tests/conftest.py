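import numpy as np
import pytest

from oktrack import SceneSpec, generate_scene, run_tracker


@pytest.fixture(scope="session")
def cw_scene():
    """One default clockwise scene (frames + ground truth), rendered once."""
    spec = SceneSpec(direction="clockwise", rng_seed=5)
    frames, truth = generate_scene(spec)
    return spec, frames, truth


@pytest.fixture(scope="session")
def cw_result(cw_scene):
    _, frames, _ = cw_scene
    return run_tracker(frames)


@pytest.fixture(scope="session")
def mirrored_result(cw_scene):
    _, frames, _ = cw_scene
    return run_tracker([f[:, ::-1] for f in frames])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
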