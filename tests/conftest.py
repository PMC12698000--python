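import numpy as np
import pytest

from baplearn import rng, spikegen
from baplearn.fixtures import make_fixture, toy_input_spec
from baplearn.protocols import make_trial_config
from baplearn.simulation import run_trial


@pytest.fixture(scope="session")
def toy_stream():
    stream, schedule = make_fixture("toy_stream", seed=1)
    return stream, schedule


@pytest.fixture(scope="session")
def toy_template():
    return make_fixture("toy_template", seed=1)


@pytest.fixture(scope="session")
def fig1_spec():
    return spikegen.InputStreamSpec()


@pytest.fixture(scope="session")
def tuning_batch():
    """Session-wide batch of standard 20 s spike-trace tuning trials.

    Shared by the convergence-speed, jitter-robustness and homeostasis
    acceptance checks so the heavy simulations run once."""
    results = []
    for k in range(64):
        cfg = make_trial_config(900_000 + k, "spike_trace")
        results.append(run_trial(cfg))
    return results


@pytest.fixture()
def rng_fixed():
    return np.random.default_rng(12345)
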