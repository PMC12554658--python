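import numpy as np
import pytest

import phenohull as ph

# Reference hull of one real silhouette at the 90-degree view: left and
# right chain corner coordinates, top -> bottom, (vertical, lateral).
TABLE3_LEFT = np.array(
    [
        (5.47, 0.01),
        (5.05, -0.26),
        (4.22, -0.65),
        (3.39, -0.69),
        (2.05, -0.45),
        (0.48, 0.04),
    ]
)
TABLE3_RIGHT = np.array(
    [
        (5.47, 0.01),
        (4.95, 0.48),
        (3.95, 0.57),
        (3.07, 0.64),
        (2.55, 0.62),
        (0.48, 0.04),
    ]
)

# Published 20-plant validation set: (truth, predicted) label pairs.
C, T = "cylinder", "tower"
TABLE8_PAIRS = [
    (C, C), (T, T),
    (C, C), (C, T),
    (T, T), (C, C),
    (T, C), (T, T),
    (C, T), (T, T),
    (T, C), (T, T),
    (C, C), (T, T),
    (T, T), (C, C),
    (C, T), (C, C),
    (C, C), (C, C),
]


@pytest.fixture
def table3_left():
    return TABLE3_LEFT.copy()


@pytest.fixture
def table3_right():
    return TABLE3_RIGHT.copy()


@pytest.fixture
def table8_pairs():
    return list(TABLE8_PAIRS)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_cloud(rng):
    n = 1000
    return ph.PointCloud(
        coords=rng.uniform(-10, 10, (n, 3)),
        colors=rng.integers(0, 256, (n, 3)),
        name="random",
    )
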