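"""Post-synaptic pulse models as linear filters of order L.

The network mean field E(t) is the superposition of unit-area pulses,
generated by the ODE  E^(L) = sum_i a_i E^(i) + (K/N) sum_n delta(t-t_n)
whose characteristic polynomial is prod_k (s + alpha_k); the gain
K = prod_k alpha_k makes each single pulse have unit area.  L-1 is the
order of the lowest discontinuous derivative, so L controls pulse
smoothness: L=0 are instantaneous delta-pulses (no field dynamics), L=1
discontinuous exponentials, L=2 with a double pole alpha the classical
alpha-pulse  E_s(t) = alpha^2 t exp(-alpha t).

Internally the field state is the companion vector
v = (E, E', ..., E^(L-1)); each spike adds K/N to the last component.
beta-pulses are alpha-pulses whose rate scales with the network size,
alpha = beta N, so that the pulse width stays comparable to the network
interspike interval T0/N.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Optional, Tuple

import numpy as np
from scipy.linalg import expm

__all__ = ["PulseModel", "field_step_alpha"]


@dataclass(frozen=True)
class PulseModel:
    order_L: int
    poles: Tuple[float, ...]
    scaled_with_N: bool = False
    beta: Optional[float] = None

    def __post_init__(self) -> None:
        if self.order_L != len(self.poles):
            raise ValueError("order_L must equal the number of poles")
        if any(a <= 0 for a in self.poles):
            raise ValueError("pulse poles must be positive rates")
        if self.scaled_with_N and self.beta is None:
            raise ValueError("beta-pulses need the scale rate beta")

    # -- constructors -------------------------------------------------
    @staticmethod
    def delta() -> "PulseModel":
        """L=0: instantaneous pulses, no field dynamics."""
        return PulseModel(order_L=0, poles=())

    @staticmethod
    def exponential(alpha: float) -> "PulseModel":
        return PulseModel(order_L=1, poles=(alpha,))

    @staticmethod
    def alpha_pulse(alpha: float) -> "PulseModel":
        return PulseModel(order_L=2, poles=(alpha, alpha))

    @staticmethod
    def beta_pulse(beta: float) -> "PulseModel":
        """alpha-pulse with N-scaled rate; resolve(N) fixes alpha = beta*N."""
        return PulseModel(order_L=2, poles=(beta, beta), scaled_with_N=True, beta=beta)

    @staticmethod
    def general(poles) -> "PulseModel":
        return PulseModel(order_L=len(tuple(poles)), poles=tuple(float(p) for p in poles))

    def resolve(self, N: int) -> "PulseModel":
        """Concrete pulse for a network of size N (binds alpha = beta*N)."""
        if not self.scaled_with_N:
            return self
        a = self.beta * N
        return PulseModel(order_L=2, poles=(a, a), scaled_with_N=True, beta=self.beta)

    # -- basic scalars ------------------------------------------------
    @property
    def is_delta(self) -> bool:
        return self.order_L == 0

    @property
    def gain_K(self) -> float:
        return float(np.prod(self.poles)) if self.poles else 1.0

    @property
    def pole_sum_S(self) -> float:
        return float(np.sum(self.poles)) if self.poles else 0.0

    @cached_property
    def companion(self) -> np.ndarray:
        """C with char. polynomial prod_k (s + alpha_k); v' = C v."""
        L = self.order_L
        coeffs = np.atleast_1d(np.poly(np.array([-a for a in self.poles])))  # s^L + ...
        C = np.zeros((L, L))
        if L > 1:
            C[:-1, 1:] = np.eye(L - 1)
        C[-1, :] = -coeffs[1:][::-1]
        return C

    def jump(self, N: int) -> np.ndarray:
        """Field-state increment caused by one incoming spike."""
        v = np.zeros(self.order_L)
        v[-1] = self.gain_K / N
        return v

    # -- propagator ---------------------------------------------------
    @cached_property
    def _degenerate_alpha(self) -> Optional[float]:
        if self.order_L == 2 and self.poles[0] == self.poles[1]:
            return self.poles[0]
        return None

    @cached_property
    def _eig(self):
        lam, V = np.linalg.eig(self.companion)
        if np.min(np.abs(lam[:, None] - lam[None, :]) + np.eye(self.order_L)) < 1e-9:
            return None  # repeated poles -> expm fallback
        return lam, V, np.linalg.inv(V)

    def propagator(self, t: float) -> np.ndarray:
        """exp(C t); exact closed forms for L=1 and the double pole."""
        L = self.order_L
        if L == 0:
            return np.zeros((0, 0))
        if L == 1:
            return np.array([[np.exp(-self.poles[0] * t)]])
        a = self._degenerate_alpha
        if a is not None:
            e = np.exp(-a * t)
            return e * np.array([[1.0 + a * t, t],
                                 [-a * a * t, 1.0 - a * t]])
        eig = self._eig
        if eig is None:
            return expm(self.companion * t)
        lam, V, Vi = eig
        return (V * np.exp(lam * t)) @ Vi

    def E_row(self, t):
        """First row of exp(C t) for scalar or array t -> shape t + (L,).

        E_row(t)[..., m] is the E-component response at time t to a unit
        perturbation of field component m; also gives the free field
        E(t) = E_row(t) @ v0.
        """
        t = np.asarray(t, float)
        L = self.order_L
        if L == 1:
            return np.exp(-self.poles[0] * t)[..., None]
        a = self._degenerate_alpha
        if a is not None:
            e = np.exp(-a * t)
            return np.stack([e * (1.0 + a * t), e * t], axis=-1)
        eig = self._eig
        if eig is not None:
            lam, V, Vi = eig
            phases = np.exp(np.multiply.outer(t, lam))  # t-shape x L
            return np.real(np.einsum("...k,k,km->...m", phases, V[0, :], Vi))
        flat = np.ravel(t)
        rows = np.stack([expm(self.companion * ti)[0, :] for ti in flat])
        return rows.reshape(t.shape + (L,))

    # -- field map across one interspike interval ---------------------
    def field_step(self, v: np.ndarray, T: float, N: int) -> np.ndarray:
        """Propagate the field state over duration T >= 0 and apply the
        end-of-interval spike jump K/N on the highest derivative."""
        if T < 0:
            raise ValueError("field_step needs a non-negative duration")
        return self.propagator(T) @ np.asarray(v, float) + self.jump(N)

    def fixed_point(self, T: float, N: int) -> np.ndarray:
        """Post-spike field state that is T-periodic under field_step."""
        L = self.order_L
        M = np.eye(L) - self.propagator(T)
        return np.linalg.solve(M, self.jump(N))

    def ratio_R(self, T0: float, N: int) -> float:
        """R = N / (T0 alpha): single-pulse width over mean interspike time."""
        if self.is_delta:
            return 0.0
        return N / (T0 * max(self.resolve(N).poles))


def field_step_alpha(E: float, P: float, T: float, pulse: PulseModel, N: int):
    """Closed-form alpha-pulse field map in the (E, P) variables.

    P = alpha E + E'; over an interval of duration T,
    E' = exp(-alpha T)(E + T P),  P' = exp(-alpha T) P + alpha^2/N,
    the final jump accounting for the spike received at the interval end.
    """
    if pulse.order_L != 2 or pulse.poles[0] != pulse.poles[1]:
        raise ValueError("field_step_alpha is for alpha-pulses (double pole)")
    if T < 0:
        raise ValueError("negative duration")
    a = pulse.poles[0]
    e = np.exp(-a * T)
    return e * (E + T * P), e * P + a * a / N


def v_from_EP(pulse: PulseModel, E: float, P: float) -> np.ndarray:
    """Companion state (E, E') from the alpha-pulse pair (E, P)."""
    a = pulse.poles[0]
    return np.array([E, P - a * E])


def EP_from_v(pulse: PulseModel, v: np.ndarray):
    a = pulse.poles[0]
    return float(v[0]), float(a * v[0] + v[1])
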