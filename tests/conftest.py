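import numpy as np
import pytest

from pulsestab.config import NetworkConfig
from pulsestab.event_driven import NetworkState, event_step
from pulsestab.fields import field_catalog
from pulsestab.pulses import PulseModel


@pytest.fixture(scope="session")
def lif():
    return field_catalog("F0", 1.3)


@pytest.fixture(scope="session")
def f1():
    return field_catalog("F1", 1.3)


@pytest.fixture(scope="session")
def alpha3():
    return PulseModel.alpha_pulse(3.0)


def finite_difference_jacobian(cfg: NetworkConfig, base_vec: np.ndarray,
                               n_steps: int = 1, h: float = 1e-6) -> np.ndarray:
    """Centered finite-difference Jacobian of n_steps of the event-driven
    map, the brute-force oracle for the analytic Floquet matrices."""
    N = cfg.N
    dim = len(base_vec)

    def apply(vec):
        st = NetworkState(vec[:N - 1].copy(), vec[N - 1:].copy())
        for _ in range(n_steps):
            st, _ = event_step(st, cfg)
        return st.vector

    J = np.zeros((dim, dim))
    for i in range(dim):
        vp = base_vec.copy()
        vp[i] += h
        vm = base_vec.copy()
        vm[i] -= h
        J[:, i] = (apply(vp) - apply(vm)) / (2.0 * h)
    return J
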