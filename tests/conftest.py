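import numpy as np
import pytest

from tuftpipe.synthdata import (PopulationConfig, TaskConfig, generate_session,
                                render_movie)


@pytest.fixture(scope="session")
def small_task():
    return TaskConfig(n_trials=30)


@pytest.fixture(scope="session")
def small_session(small_task):
    return generate_session(small_task, seed=7)


@pytest.fixture(scope="session")
def small_movie(small_session):
    """64-px movie with 6 planted dendrites over the 30-trial session."""
    pop = PopulationConfig(n_dendrites=6)
    stack, gt = render_movie(small_session, pop, seed=3, frame_size_px=64)
    return stack, gt


@pytest.fixture
def rng():
    return np.random.default_rng(0)
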