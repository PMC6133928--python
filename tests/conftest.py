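import numpy as np
import pytest

from saltdyn import Frame, Trajectory


@pytest.fixture
def cubic_frame():
    """Three atoms in a 4 nm cube, one pair split across the boundary."""
    pos = np.array([[0.1, 0.0, 0.0], [3.9, 0.0, 0.0], [1.0, 2.0, 3.0]])
    return Frame(pos, box=(4.0, 4.0, 4.0), time=0.0)


@pytest.fixture
def two_frame_traj(cubic_frame):
    second = Frame(cubic_frame.positions + 0.05, cubic_frame.box, time=0.5)
    return Trajectory([cubic_frame, second], atom_labels=["OW", "HW", "LI"])


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
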