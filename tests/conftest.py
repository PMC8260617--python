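import warnings

import numpy as np
import pytest

from pursuitdecode import inverse, neurosim, workbench

# the ARD fits warn when flagged non-converged; tests assert on flags instead
warnings.filterwarnings("ignore", message="SLiR fit did not converge")
warnings.filterwarnings("ignore", message="variational estimation did not converge")


@pytest.fixture(scope="session")
def small_space():
    return neurosim.make_source_space(150, seed=0)


@pytest.fixture(scope="session")
def small_spec(small_space):
    return neurosim.make_default_subpopulations(small_space, seed=1)


@pytest.fixture(scope="session")
def small_forward(small_space):
    return neurosim.make_forward_model(small_space, n_sensors=32, seed=2)


@pytest.fixture(scope="session")
def replicate_data():
    """Ground-truth decoding data for one seeded replicate (5 tasks x 10 trials)."""
    task_data, space, spec = workbench.simulate_replicate_task_data(
        seed=42, n_dipoles=60, n_trials=10
    )
    return task_data, space, spec


@pytest.fixture(scope="session")
def overt_sensor_run(small_space, small_spec, small_forward):
    """A small overt-task sensor simulation with its preprocessed trials."""
    sim = neurosim.simulate_task(
        "overt_0.5", small_space, small_spec, small_forward, n_trials=8, seed=10
    )
    pre = inverse.preprocess(sim.trials)
    return sim, pre


@pytest.fixture(scope="session")
def smoothing(small_space, small_forward):
    return inverse.build_smoothing(small_space, small_forward.G, reduction=4)
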