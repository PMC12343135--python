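import numpy as np
import pytest

from myomorph import (
    Centerline,
    ImagingSpec,
    MyofibrilSpec,
    render_ground_truth,
    simulate_image,
)

PIXEL = 0.05  # um/px

STRAIGHT = MyofibrilSpec(
    n_sarcomeres=6, sarcomere_length=3.2, diameter=1.5, origin=(2.0, 3.5)
)
CANVAS = (140, 470)


@pytest.fixture(scope="session")
def imaging():
    return ImagingSpec(pixel_size=PIXEL, rng_seed=0)


@pytest.fixture(scope="session")
def straight_spec():
    return STRAIGHT


@pytest.fixture(scope="session")
def ground_truth(imaging):
    return render_ground_truth([STRAIGHT], imaging, CANVAS)


@pytest.fixture(scope="session")
def noiseless_image(imaging):
    """Blurred but noise-free single straight fibril."""
    return simulate_image([STRAIGHT], imaging, CANVAS, no_noise=True)


@pytest.fixture(scope="session")
def noisy_image(imaging):
    """Full noise model, fixed seed."""
    return simulate_image([STRAIGHT], imaging, CANVAS)


@pytest.fixture(scope="session")
def true_centerline():
    """Exact axis of the straight fixture as a Centerline."""
    s = np.linspace(0.0, STRAIGHT.length, 50)
    x, y = STRAIGHT.axis_point(s)
    return Centerline.from_points(np.column_stack([x, y]), smoothing=0.0)


@pytest.fixture(scope="session")
def crossing_image(imaging):
    s1 = MyofibrilSpec(6, 3.2, 1.5, orientation=15, origin=(2.0, 2.5))
    s2 = MyofibrilSpec(6, 3.2, 1.5, orientation=-15, origin=(2.0, 7.5))
    return simulate_image([s1, s2], imaging, (220, 470))
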