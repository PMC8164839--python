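import numpy as np
import pytest

from cshin.morphometry import CellContour


@pytest.fixture
def circle_contour():
    """Factory: regular n-gon discretization of a circle."""

    def make(radius: float = 100.0, n: int = 4096, center=(0.0, 0.0)) -> CellContour:
        t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        return CellContour(
            np.column_stack(
                [center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)]
            )
        )

    return make


@pytest.fixture
def unit_square():
    return CellContour([(0, 0), (1, 0), (1, 1), (0, 1)])
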