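import numpy as np
import pytest

from contourhsc import PhantomSpec, SliceContour, Structure, generate_phantom


@pytest.fixture
def unit_square():
    return SliceContour([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)])


@pytest.fixture
def small_phantom():
    """A quick bladder-like phantom for unit tests."""
    return generate_phantom(
        PhantomSpec(n_slices=10, max_radius=20.0, points_per_slice=24,
                    noise_amp=0.5, seed=7)
    )


@pytest.fixture(scope="session")
def default_phantom():
    """The default study phantom (28 slices, 64 points/slice)."""
    return generate_phantom(PhantomSpec())


def square_structure(side, z=0.0, origin=(0.0, 0.0), thickness=1.0, name="sq"):
    x0, y0 = origin
    pts = [
        (x0, y0, z), (x0 + side, y0, z),
        (x0 + side, y0 + side, z), (x0, y0 + side, z),
    ]
    return Structure(name, [SliceContour(pts)], thickness)


def circle_contour(radius, n=256, z=0.0, center=(0.0, 0.0)):
    th = np.arange(n) * (2 * np.pi / n)
    pts = np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th),
         np.full(n, z)]
    )
    return SliceContour(pts)
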