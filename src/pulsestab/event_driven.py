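"""Exact spike-to-spike evolution and the splay-state fixed point.

Between two consecutive network spikes the mean field evolves freely
(the pulse ODE is linear, so the field map is exact), and each membrane
potential follows  Xdot = F(X) + g E(t)  with E(t) known in closed form.
The event-driven map advances the ordered state (X^1 >= ... >= X^{N-1},
X^N = 0) across one interspike interval: the crossing time T solves the
threshold condition Phi(X^1, field, T) = 1, all potentials are
propagated by the flow Phi, labels are shifted backward (comoving
frame), the firing neuron is reset to 0 and the field receives the
end-of-interval spike jump.

The splay state — all neurons on the same periodic orbit with evenly
spaced time shifts — is a fixed point of this map.  Finding it reduces
to a one-dimensional root solve on the interspike interval T: given T
the periodic field state is known in closed form, and the membrane
potentials follow by iterating the flow backward from X^N = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .config import NetworkConfig
from .fields import VelocityField
from .pulses import PulseModel, EP_from_v

__all__ = ["NetworkState", "SplayFixedPoint", "FlowMap", "DeltaFlow",
           "event_step", "splay_fixed_point", "flow_map"]

_RTOL = 1e-12
_ATOL = 1e-14


@dataclass
class NetworkState:
    """Ordered network state on the spike Poincare section.

    potentials: X^1 >= ... >= X^{N-1}; X^N = 0 is implicit (the neuron
    reset at the previous spike).  field_v is the companion field vector
    (empty for delta-pulses).  time accumulates the interspike intervals.
    """

    potentials: np.ndarray
    field_v: np.ndarray
    time: float = 0.0

    def copy(self) -> "NetworkState":
        return NetworkState(self.potentials.copy(), self.field_v.copy(), self.time)

    @property
    def vector(self) -> np.ndarray:
        """Flat state (X^1..X^{N-1}, field components) for Jacobian work."""
        return np.concatenate([self.potentials, self.field_v])


@dataclass
class SplayFixedPoint:
    """Splay state of the event-driven map.

    interspike_T is the network interspike interval (the period of the
    map); potentials_X are the N-1 ordered values with X^N = 0 implicit;
    field_v is the post-spike periodic field state.
    """

    config: NetworkConfig
    interspike_T: float
    potentials_X: np.ndarray
    field_v: np.ndarray
    residual: float

    @property
    def period_T0(self) -> float:
        """Single-neuron period T0 = N * T."""
        return self.config.N * self.interspike_T

    @property
    def E_tilde(self) -> float:
        if self.config.resolved_pulse.is_delta:
            return 1.0 / self.period_T0
        return float(self.field_v[0])

    @property
    def P_tilde(self) -> float:
        """Auxiliary alpha-pulse variable P = alpha E + E'."""
        return EP_from_v(self.config.resolved_pulse, self.field_v)[1]

    @property
    def ratio_R(self) -> float:
        return self.config.resolved_pulse.ratio_R(self.period_T0, self.config.N)

    def state(self) -> NetworkState:
        return NetworkState(self.potentials_X.copy(), self.field_v.copy())


class FlowMap:
    """The propagator Phi of a single membrane potential.

    propagate(X0, v0, T) integrates Xdot = F(X) + g E(t) with the field
    E(t) generated freely from the post-spike state v0.  Partial
    derivatives with respect to X0 and the field components are computed
    by integrating the variational equations alongside (never by finite
    differences).  For the leaky integrate-and-fire field F0 = a - X an
    exact closed form is available (``closed_form=True``).
    """

    def __init__(self, field: VelocityField, g: float, pulse: PulseModel,
                 closed_form: bool = False):
        if closed_form and field.name != "F0":
            raise ValueError("closed-form propagator exists only for the linear field F0")
        self.field = field
        self.g = g
        self.pulse = pulse
        self.closed_form = closed_form
        self._L = pulse.order_L

    # -- field forcing ------------------------------------------------
    def E_of_t(self, t, v0):
        if self._L == 0:
            return np.zeros_like(np.asarray(t, float))
        return self.pulse.E_row(t) @ np.asarray(v0, float)

    # -- closed form for F0 + alpha pulses ----------------------------
    def _propagate_lif(self, X0, v0, T):
        a = self.field.param_a
        al = self.pulse.poles[0]
        E0, P0 = EP_from_v(self.pulse, v0)
        mu = 1.0 - al
        t = float(T)
        if abs(mu) > 1e-8:
            emt = np.exp(mu * t)
            J = E0 * (emt - 1.0) / mu + P0 * (t * emt / mu - (emt - 1.0) / mu ** 2)
        else:  # alpha ~ 1: series-safe quadratic limit
            J = E0 * t + P0 * t * t / 2.0
        return np.exp(-t) * (np.asarray(X0, float) + self.g * J) + a * (1.0 - np.exp(-t))

    # -- generic numeric propagation ----------------------------------
    def propagate(self, X0, v0, T: float):
        """End value(s) of the potential(s) after duration T (may be < 0)."""
        if self.closed_form:
            return self._propagate_lif(X0, v0, T)
        X0 = np.atleast_1d(np.asarray(X0, float))
        if T == 0.0:
            out = X0.copy()
        else:
            def rhs(t, x):
                return self.field.evaluate(x) + self.g * self.E_of_t(t, v0)
            sol = solve_ivp(rhs, (0.0, T), X0, method="DOP853",
                            rtol=_RTOL, atol=_ATOL)
            if not sol.success:
                raise RuntimeError(f"flow integration failed: {sol.message}")
            out = sol.y[:, -1]
        return out if np.ndim(X0) and len(out) > 1 else float(out[0])

    def propagate_with_partials(self, X0, v0, T: float):
        """Returns (X_T, dX/dX0, dX/dv0 (length-L array), Xdot at T).

        Vectorized over an array of starting points X0; the variational
        equations  D' = F'(X) D,  b_m' = F'(X) b_m + g (e^{Ct})_{0m}
        are appended to the flow and integrated with the same scheme.
        """
        X0 = np.atleast_1d(np.asarray(X0, float))
        n = len(X0)
        L = self._L
        y0 = np.zeros(n * (2 + L))
        y0[:n] = X0
        y0[n:2 * n] = 1.0  # D(0) = 1

        def rhs(t, y):
            x = y[:n]
            Fp = np.asarray(self.field.derivative(x), float)
            out = np.empty_like(y)
            out[:n] = self.field.evaluate(x) + self.g * self.E_of_t(t, v0)
            out[n:2 * n] = Fp * y[n:2 * n]
            if L:
                row = self.pulse.E_row(t)  # (L,)
                for m in range(L):
                    sl = slice((2 + m) * n, (3 + m) * n)
                    out[sl] = Fp * y[sl] + self.g * row[m]
            return out

        if T == 0.0:
            XT, D = X0.copy(), np.ones(n)
            b = np.zeros((n, L))
        else:
            sol = solve_ivp(rhs, (0.0, T), y0, method="DOP853",
                            rtol=_RTOL, atol=_ATOL)
            if not sol.success:
                raise RuntimeError(f"variational integration failed: {sol.message}")
            y = sol.y[:, -1]
            XT, D = y[:n], y[n:2 * n]
            b = y[2 * n:].reshape(L, n).T if L else np.zeros((n, 0))
        Xdot = np.asarray(self.field.evaluate(XT), float) + self.g * float(self.E_of_t(T, v0))
        return XT, D, b, Xdot

    def crossing_time(self, X1: float, v0, t_max: float) -> float:
        """First time at which the trajectory from X1 reaches threshold 1.

        Searches forward on [0, t_max]; if the potential already sits at
        or above threshold, a small backward search is performed so that
        near-degenerate (synchronous) states remain well-defined.
        """
        if self.closed_form:
            lo, hi = 0.0, t_max
            f = lambda t: self._propagate_lif(X1, v0, t) - 1.0
            if f(0.0) >= 0.0:
                lo = -min(0.5, t_max)
                if f(lo) >= 0.0:
                    raise RuntimeError("no threshold crossing (backward search failed)")
                hi = 0.0
            else:
                # expand until sign change
                while f(hi) < 0.0:
                    hi *= 2.0
                    if hi > 64.0 * t_max:
                        raise RuntimeError("no threshold crossing within the cap time")
            return brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)

        def rhs(t, x):
            return self.field.evaluate(x) + self.g * self.E_of_t(t, v0)

        def hit(t, x):
            return x[0] - 1.0
        hit.terminal = True
        hit.direction = 1.0

        if X1 >= 1.0:
            if X1 == 1.0:
                return 0.0
            # tiny backward bracket around t = 0
            f = lambda t: self.propagate(X1, v0, t) - 1.0
            lo = -1e-6
            while f(lo) > 0.0:
                lo *= 4.0
                if lo < -0.5:
                    raise RuntimeError("no threshold crossing (backward search failed)")
            return brentq(f, lo, 0.0, xtol=1e-15, rtol=8.9e-16)

        sol = solve_ivp(rhs, (0.0, t_max), [X1], method="DOP853",
                        rtol=_RTOL, atol=_ATOL, events=hit)
        if not sol.success:
            raise RuntimeError(f"threshold integration failed: {sol.message}")
        if not len(sol.t_events[0]):
            raise RuntimeError(
                "no threshold crossing within the cap time: configuration "
                "appears quiescent (check F positivity and coupling)")
        return float(sol.t_events[0][0])


def flow_map(field: VelocityField, pulse: PulseModel, g: float = 0.0,
             closed_form: bool = False) -> FlowMap:
    """Factory mirroring FlowMap(field, g, pulse, closed_form)."""
    return FlowMap(field, g, pulse, closed_form=closed_form)


class DeltaFlow:
    """Autonomous flow utilities for delta-pulse networks.

    With instantaneous pulses there is no field dynamics: between events
    Xdot = F(X), and every spike kicks all other potentials by g/N.
    Propagation uses the time-of-flight coordinate Theta(X) = int dX/F
    and its inverse, both built once from dense-output integrations.
    """

    X_MIN = -2.0  # inhibitory kicks may push potentials slightly below 0

    def __init__(self, field: VelocityField):
        self.field = field
        solT = solve_ivp(lambda x, th: 1.0 / np.asarray(field.evaluate(x), float),
                         (self.X_MIN, 1.0), [0.0], method="DOP853",
                         rtol=1e-13, atol=1e-15, dense_output=True)
        solX = solve_ivp(lambda t, x: np.asarray(field.evaluate(x), float),
                         (0.0, float(solT.y[0, -1]) * 1.0000001), [self.X_MIN],
                         method="DOP853", rtol=1e-13, atol=1e-15, dense_output=True)
        if not (solT.success and solX.success):
            raise RuntimeError("time-of-flight construction failed")
        self._theta = solT.sol
        self._xinv = solX.sol
        self._theta1 = float(solT.y[0, -1])

    def theta(self, x):
        return self._theta(np.clip(np.asarray(x, float), self.X_MIN, 1.0))[0] \
            if np.ndim(x) else float(self._theta(float(np.clip(x, self.X_MIN, 1.0)))[0])

    def advance(self, x, T: float):
        """psi_T(x): flow by time T (requires the result to stay <= 1)."""
        th = self.theta(np.asarray(x, float)) + T
        if np.any(np.asarray(th) > self._theta1 + 1e-12):
            raise RuntimeError("delta-pulse flow left the unit interval")
        out = self._xinv(np.clip(th, 0.0, self._theta1))[0]
        return out if np.ndim(x) else float(out)

    def time_to_threshold(self, x) -> float:
        return self._theta1 - self.theta(x)


def _t_cap(config: NetworkConfig) -> float:
    return 40.0 * config.field.free_period()


def event_step(state: NetworkState, config: NetworkConfig,
               flow: Optional[FlowMap] = None) -> Tuple[NetworkState, float]:
    """One step of the event-driven map: returns (new state, interspike T).

    Ordering of the potentials is preserved automatically (all neurons
    feel the same field, so the 1-D trajectories cannot cross); it is
    re-checked after the step and a violation is reported as an internal
    integration failure.
    """
    pulse = config.resolved_pulse
    N = config.N
    X = state.potentials
    if len(X) != N - 1:
        raise ValueError("state has wrong dimension for this configuration")

    if pulse.is_delta:
        dflow = flow if isinstance(flow, DeltaFlow) else DeltaFlow(config.field)
        T = dflow.time_to_threshold(X[0])
        kick = config.g / N
        shifted = np.concatenate([X[1:], [0.0]])
        newX = dflow.advance(shifted, T) + kick
        if newX[0] >= 1.0:
            raise RuntimeError("delta-pulse avalanche: kick pushed a neuron "
                               "across threshold (excitatory g too large)")
        new = NetworkState(newX, state.field_v.copy(), state.time + T)
    else:
        fl = flow if isinstance(flow, FlowMap) else FlowMap(config.field, config.g, pulse)
        v0 = state.field_v
        T = fl.crossing_time(float(X[0]), v0, _t_cap(config))
        shifted = np.concatenate([X[1:], [0.0]])
        newX = np.atleast_1d(fl.propagate(shifted, v0, T))
        new_v = pulse.propagator(T) @ v0 + pulse.jump(N)
        new = NetworkState(newX, new_v, state.time + T)

    # tolerance admits near-degenerate (synchronous) states probed by
    # infinitesimal perturbations; gross violations mean integrator failure
    if np.any(np.diff(new.potentials) > 1e-6):
        raise RuntimeError("ordering violated after event step (integration failure)")
    return new, T


def _splay_residual(T: float, config: NetworkConfig, rtol: float = 1e-8):
    """x(N T) - 1 for the single periodically-forced trajectory from 0.

    Coarse residual used only to bracket and pre-locate the interspike
    interval; the returned fixed point is always polished afterwards
    with the kink-free per-interval chain.
    """
    pulse = config.resolved_pulse
    N = config.N
    v = pulse.fixed_point(T, N)

    def E_per(t):
        return pulse.E_row(np.mod(t, T)) @ v

    sol = solve_ivp(lambda t, x: np.asarray(config.field.evaluate(x), float)
                    + config.g * E_per(t),
                    (0.0, N * T), [0.0], method="DOP853",
                    rtol=rtol, atol=rtol * 1e-2, max_step=T)
    if not sol.success:
        raise RuntimeError(f"splay residual integration failed: {sol.message}")
    return float(sol.y[0, -1]) - 1.0


def _splay_residual_delta(T: float, config: NetworkConfig, dflow: DeltaFlow,
                          want_X: bool = False):
    """Residual in time units: T minus the last segment's time to threshold.

    Positive when the trial interspike interval T is too long (the chain
    overshoots the threshold); intermediate overshoots also count as
    positive so the bracketing scan sees a sign change.
    """
    N = config.N
    kick = config.g / N
    x = 0.0
    chain = [0.0]
    for _ in range(N - 1):
        tt = dflow.time_to_threshold(x)
        if T > tt:
            return (T - tt + 1.0, None) if want_X else T - tt + 1.0
        x = dflow.advance(x, T) + kick
        chain.append(x)
    res = T - dflow.time_to_threshold(x)
    if want_X:
        return res, np.array(chain[::-1][:-1])  # X^1 .. X^{N-1}
    return res


def splay_fixed_point(config: NetworkConfig) -> SplayFixedPoint:
    """Construct the splay state of the event-driven map (unforced, A=0).

    Outer 1-D root solve on the interspike interval T; inner backward
    iteration of the flow from X^N = 0 with the closed-form periodic
    field.  The residual |Phi(X^1) - 1| of the returned point is below
    1e-10 by construction of the bracketing solve.
    """
    if config.forcing_A != 0.0:
        raise ValueError("splay fixed points are defined for the unforced network")
    pulse = config.resolved_pulse
    N = config.N
    T_free = config.field.free_period() / N

    if pulse.is_delta:
        dflow = DeltaFlow(config.field)
        res = lambda T: _splay_residual_delta(T, config, dflow)
        xtol = 1e-14
    else:
        res = lambda T: _splay_residual(T, config)
        xtol = 1e-8 * T_free  # coarse; the chain polish below finishes the job

    # expand a bracket away from the uncoupled estimate: the residual
    # increases with the trial interval (longer flight overshoots)
    def try_res(T):
        try:
            return res(T)
        except (RuntimeError, np.linalg.LinAlgError):
            return None

    Ta, va = T_free, try_res(T_free)
    grow = 1.25
    bracket = None
    for _ in range(60):
        if va is None:
            Ta *= 0.8
            va = try_res(Ta)
            continue
        Tb = Ta * grow if va < 0 else Ta / grow
        vb = try_res(Tb)
        if vb is not None and np.sign(vb) != np.sign(va):
            bracket = (min(Ta, Tb), max(Ta, Tb))
            break
        Ta, va = Tb, vb
    if bracket is None:
        raise RuntimeError(
            "no sign change of the splay residual while bracketing the "
            "interspike interval; inspect the coupling strength and field")
    T = brentq(res, *bracket, xtol=xtol, rtol=8.9e-16, maxiter=200)

    if pulse.is_delta:
        resid, Xs = _splay_residual_delta(T, config, dflow, want_X=True)
        v = np.zeros(0)
    else:
        fl = FlowMap(config.field, config.g, pulse)

        def chain(Tc):
            # backward iteration from X^N = 0, one smooth interval at a time
            vc = pulse.fixed_point(Tc, N)
            Xc = np.empty(N - 1)
            x = 0.0
            for j in range(N - 2, -1, -1):
                x = fl.propagate(x, vc, Tc)
                Xc[j] = x
            return fl.propagate(Xc[0], vc, Tc) - 1.0, Xc, vc

        # polish the coarse root with the per-interval (kink-free) residual
        resid, Xs, v = chain(T)
        T1, r1 = T * (1.0 + 1e-7), None
        for _ in range(10):
            if abs(resid) < 1e-12:
                break
            if r1 is None:
                r1, _, _ = chain(T1)
            slope = (r1 - resid) / (T1 - T)
            T1, r1 = T, resid
            T = T - resid / slope
            resid, Xs, v = chain(T)
    if abs(resid) > 1e-9:
        raise RuntimeError(f"splay fixed point residual too large: {resid:.3e}")
    return SplayFixedPoint(config=config, interspike_T=float(T),
                           potentials_X=Xs, field_v=v, residual=float(resid))
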