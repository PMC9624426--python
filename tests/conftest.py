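import numpy as np
import pytest

from socioglia.morphometry import NeuronArbor


@pytest.fixture
def y_arbor() -> NeuronArbor:
    """Symmetric Y: 5 um trunk, two 5 um daughters."""
    c, s = 5 * np.cos(0.6), 5 * np.sin(0.6)
    return NeuronArbor(
        ids=[1, 2, 3, 4],
        types=[1, 3, 3, 3],
        xyz=[[0, 0, 0], [5, 0, 0], [5 + c, s, 0], [5 + c, -s, 0]],
        radius=[1.0] * 4,
        parent=[-1, 1, 2, 2],
    )


@pytest.fixture
def path_arbor() -> NeuronArbor:
    """Unbranched 10 um path in two 5 um edges."""
    return NeuronArbor(
        ids=[1, 2, 3],
        types=[1, 3, 3],
        xyz=[[0, 0, 0], [5, 0, 0], [10, 0, 0]],
        radius=[1.0] * 3,
        parent=[-1, 1, 2],
    )
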