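import numpy as np
import pandas as pd
import pytest

from tomospat.particles import COLUMNS, ParticleSet


def make_set(positions, states=None, eulers=None, tomogram="tomo_1", provenance="test"):
    """Build a ParticleSet from raw arrays with sequential ids."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if states is None:
        states = ["closed"] * n
    if eulers is None:
        eulers = np.zeros((n, 3))
    tomo = [tomogram] * n if isinstance(tomogram, str) else list(tomogram)
    df = pd.DataFrame(
        {
            "particle_id": [f"p{i:04d}" for i in range(n)],
            "tomogram_id": tomo,
            "x": positions[:, 0],
            "y": positions[:, 1],
            "z": positions[:, 2],
            "phi": np.asarray(eulers)[:, 0],
            "theta": np.asarray(eulers)[:, 1],
            "psi": np.asarray(eulers)[:, 2],
            "state": states,
        },
        columns=COLUMNS,
    )
    return ParticleSet(df, provenance)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def collinear_chain():
    """Four collinear closed particles at 17 nm spacing."""
    return make_set([[i * 17.0, 0, 0] for i in range(4)])


@pytest.fixture
def star_text():
    return (
        "data_particles\n\nloop_\n"
        "_rlnCoordinateX #1\n_rlnCoordinateY #2\n_rlnCoordinateZ #3\n"
        "_rlnAngleRot #4\n_rlnAngleTilt #5\n_rlnAnglePsi #6\n"
        "_rlnMicrographName #7\n"
        "100 200 50 10 20 30 tomo_a\n"
        "300 400 80 -40 90 120 tomo_a\n"
    )
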