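import numpy as np
import pytest

from shoalkit.behavior import Track
from shoalkit.synthetic import FollowerParams, NeuronSimParams, gen_dyad, gen_traces
from shoalkit.tuning import make_schedule


@pytest.fixture(scope="session")
def follower_dyad():
    """Strongly coupled dyad, long enough for attraction chunking."""
    return gen_dyad("follower", FollowerParams(seed=11), duration_s=1200.0)


@pytest.fixture(scope="session")
def small_population():
    """400-neuron synthetic trace population with its schedule and truth table."""
    schedule = make_schedule(seed=7)
    params = NeuronSimParams(n_neurons=400, seed=7)
    traces, truth = gen_traces(params, schedule)
    return traces, schedule, truth


def random_walk_track(seed: int, duration_s: float = 600.0, fps: float = 30.0,
                      step_mm: float = 0.2) -> Track:
    rng = np.random.default_rng(seed)
    n = int(duration_s * fps)
    steps = rng.normal(0.0, step_mm, (n, 2))
    xy = np.cumsum(steps, axis=0)
    return Track(t_s=np.arange(n) / fps, x_mm=xy[:, 0], y_mm=xy[:, 1])
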