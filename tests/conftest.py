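import numpy as np
import pytest

from pharynxsim import ModelParameters, simulate_reference_protocol
from pharynxsim.integrator import SimulationTrace, reference_schedule


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def noiseless_trace(params):
    """2.1 s of the reference protocol (four commanded plateaus)."""
    return simulate_reference_protocol(params, None, t_total=2100.0)


@pytest.fixture(scope="session")
def noiseless_schedule(params):
    return reference_schedule(params, None, 2100.0)


def make_trace(times, V, params=None, dt=None):
    """Construct a synthetic trace with only the V column meaningful."""
    times = np.asarray(times, dtype=float)
    V = np.asarray(V, dtype=float)
    data = np.zeros((times.size, 9))
    data[:, 0] = V
    return SimulationTrace(times=times, data=data,
                           params=params or ModelParameters(),
                           schedule_digest="synthetic")


@pytest.fixture(scope="session")
def square_trace_factory():
    def build(t_total=1100.0, dt=0.5, levels=((100.0, 350.0, 40.0),),
              baseline=-65.0):
        times = np.arange(0.0, t_total + dt / 2, dt)
        V = np.full(times.size, baseline)
        for t0, t1, v in levels:
            V[(times >= t0) & (times < t1)] = v
        return make_trace(times, V)
    return build
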