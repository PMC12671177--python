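import numpy as np
import pytest

from clemosaic import simgen


@pytest.fixture(scope="session")
def small_scene():
    return simgen.GlandSceneParams(image_size=(128, 128), n_glands=5, seed=42)


@pytest.fixture(scope="session")
def small_frame(small_scene):
    return simgen.generate_gland_image(small_scene)


@pytest.fixture(scope="session")
def stable_translation_sequence():
    """8 frames related by known pure translations, no shear."""
    disps = ((0, 0), (6, 2), (5, -3), (7, 1), (4, 4), (6, -2), (5, 3), (6, 1))
    script = simgen.MotionScript(disps, pause_threshold=100.0, shear_gain=0.0)
    scene = simgen.GlandSceneParams(image_size=(160, 160), n_glands=8, seed=9)
    return simgen.generate_sequence(scene, script)


@pytest.fixture(scope="session")
def mixed_sequence():
    """20-frame slow-translation/brief-pause sequence, ~20% unstable."""
    scene = simgen.GlandSceneParams(image_size=(160, 160), n_glands=7, seed=3)
    script = simgen.default_motion_script(20, 0.2, seed=5)
    return simgen.generate_sequence(scene, script)


def true_transform_to(i: int, ref: int, seq) -> np.ndarray:
    """Compose ground-truth pair transforms into the frame-i -> ref map."""
    h = np.eye(3)
    if i < ref:
        for k in range(i, ref):
            h = seq.true_pair_transforms[k] @ h
    else:
        for k in range(ref, i):
            h = np.linalg.inv(seq.true_pair_transforms[k]) @ h
    return h
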