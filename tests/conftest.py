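import numpy as np
import pytest

import lltherm as L


@pytest.fixture(scope="session")
def seq():
    """Default protocol: 5° / 25 ms / TR 2000 ms, three interleaved slices."""
    return L.SequenceParams()


@pytest.fixture(scope="session")
def seq_1slice():
    return L.SequenceParams(n_slices=1)


@pytest.fixture(scope="session")
def variable_schedule():
    """The printed-constraint schedule: NA 42 x 5 head, 3 x 20 tail, 948 total."""
    return L.build_schedule(
        n_points_max=79, budget=948, head_points=5, head_na=42, tail_points=20, tail_na=3
    )


@pytest.fixture(scope="session")
def constant_schedule_12():
    return L.constant_schedule(79, 12)


@pytest.fixture(scope="session")
def five_vial_phantom():
    """S1..S5 at the measured reference temperature, from the bundled laws."""
    from lltherm.datasets import load_calibration

    return L.make_vial_phantom(
        geometry=L.default_geometry(5), temperature=24.3, calibration=load_calibration(5)
    )


@pytest.fixture(scope="session")
def b1_map():
    return L.make_flip_angle_map((64, 35), mean=4.8, sd=0.6, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
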