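import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import colloidspot as cs

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ci_cfg():
    """Small noise-free micromodel scene used throughout the suite."""
    return cs.SceneConfig.ci_scale(seed=42)


@pytest.fixture(scope="session")
def ci_scene(ci_cfg):
    seq, truth, state = cs.generate_scene(ci_cfg, return_state=True)
    return seq, truth, state


@pytest.fixture(scope="session")
def ref_frame(ci_cfg):
    """Frame 0 of the small scene with its ground truth."""
    frame, truth = cs.render_reference_frame(ci_cfg)
    return frame, truth


def three_level_frame(rng=None, shape=(32, 32), colloids=((10, 10), (20, 25)),
                      grain=10, pore=150, colloid=250):
    """Hand-built three-level frame: grain block on the left, pore elsewhere,
    plus-shaped colloids stamped at the given centres."""
    img = np.full(shape, pore, dtype=np.uint8)
    img[:, : shape[1] // 4] = grain
    for r, c in colloids:
        img[r, c] = colloid
        img[r - 1, c] = img[r + 1, c] = img[r, c - 1] = img[r, c + 1] = colloid
    return cs.GrayFrame(img)
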