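import numpy as np
import pytest

from scolioscreen.keypoints import BackKeypoints, Keypoint


def make_keypoints(
    spine_x=(400, 400, 400, 400, 400),
    spine_y=(100, 300, 500, 700, 900),
    scapula_left=(250, 260),
    scapula_right=(550, 260),
    width=800,
    height=1000,
):
    pts = [
        Keypoint(f"spine{i}", float(x), float(y))
        for i, (x, y) in enumerate(zip(spine_x, spine_y))
    ]
    pts.append(Keypoint("scapula_left", *map(float, scapula_left)))
    pts.append(Keypoint("scapula_right", *map(float, scapula_right)))
    return BackKeypoints(points=pts, image_width=width, image_height=height)


@pytest.fixture
def straight_kp():
    return make_keypoints()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def sine_spine(kind: str, amplitude: float, length: float = 800.0, x0: float = 400.0):
    """Five spine points sampled from the sine archetype family."""
    m = {"straight": 0, "C": 1, "S": 2, "multi": 3}[kind]
    t = np.linspace(0.0, length, 5)
    d = amplitude * length * np.sin(m * np.pi * t / length)
    return np.c_[x0 + d, 100.0 + t]
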