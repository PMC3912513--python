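"""Stability of the fully synchronized state.

All neurons sit on the same trajectory, so arbitrarily close to the
orbit the full period must be broken into N event-driven steps: one
finite step of length T in which the whole cluster travels from 0 to 1
and the first neuron crosses, followed by N-1 zero-length steps in
which the remaining neurons cross one after the other.  The zero-length
steps are assembled symbolically (their matrices are exact; nothing is
integrated over a vanishing interval) — precisely the bookkeeping that
makes this analysis non-trivial: each crossing shifts the perturbed
crossing time by tau = -x^1 / V^1 and the auxiliary field variable
advances in K/N increments as the neurons progressively cross.

The product of the N matrices has an (N-1)x(N-1) potential block that
is exactly diagonal with a single repeated entry Lambda_jj — the
synchronous spectrum is degenerate and independent of the network size
— plus a 2x2 (LxL) field block Omega.

The evaporation exponent Lambda_e measures the stability of a probe
neuron riding in the frozen mean field of the synchronous cluster with
no feedback; it is computed one-sidedly (probe ahead / behind) because
discontinuous pulses (exponential, delta) break the symmetry between
early and late probes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .config import NetworkConfig
from .event_driven import FlowMap
from .pulses import EP_from_v

__all__ = ["SyncStabilityResult", "sync_orbit", "sync_floquet_product",
           "evaporation_exponent"]


@dataclass
class SyncStabilityResult:
    config: NetworkConfig
    period_T: float
    field_v: np.ndarray            # post-spike periodic field state
    Lambda_jj: float               # common potential-sector multiplier
    Lambda_spread: float           # max spread of the diagonal entries
    field_multipliers: np.ndarray  # eigenvalues of the Omega block
    matrix: np.ndarray             # full N-step product

    @property
    def E_bar(self) -> float:
        return float(self.field_v[0])

    @property
    def P_bar(self) -> float:
        return EP_from_v(self.config.resolved_pulse, self.field_v)[1]

    @property
    def exponent(self) -> float:
        """Floquet exponent ln(Lambda_jj)/T of the degenerate sector."""
        return math.log(abs(self.Lambda_jj)) / self.period_T


def sync_orbit(config: NetworkConfig):
    """Period T and periodic post-spike field state of full synchrony.

    All N spikes arrive at once, so the field jump per period is the
    full gain K (N spikes of size K/N); the period solves the implicit
    threshold condition for one neuron travelling 0 -> 1 in that field.
    """
    pulse = config.resolved_pulse
    if pulse.is_delta:
        raise ValueError("synchronous-state analysis needs a field (L >= 1); "
                         "delta-pulse synchrony collapses trajectories exactly")
    flow = FlowMap(config.field, config.g, pulse)

    def vbar(T):
        L = pulse.order_L
        jump = np.zeros(L)
        jump[-1] = pulse.gain_K            # N simultaneous spikes
        return np.linalg.solve(np.eye(L) - pulse.propagator(T), jump)

    def resid(T):
        return flow.propagate(0.0, vbar(T), T) - 1.0

    T_free = config.field.free_period()
    Ta, va = T_free, resid(T_free)
    bracket = None
    for _ in range(80):
        Tb = Ta * 1.2 if va < 0 else Ta / 1.2
        vb = resid(Tb)
        if np.sign(vb) != np.sign(va):
            bracket = (min(Ta, Tb), max(Ta, Tb))
            break
        Ta, va = Tb, vb
    if bracket is None:
        raise RuntimeError("no synchronous orbit: threshold condition has no root")
    T = brentq(resid, *bracket, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    return float(T), vbar(T)


def sync_floquet_product(config: NetworkConfig) -> SyncStabilityResult:
    """Assemble and multiply the N per-crossing Jacobians of one period.

    The first (finite) step uses the variational flow partials Phi_X,
    Phi_E, Phi_P and the crossing-time linearization; the N-1 zero
    -length crossings contribute exact matrices with -V^j/V^1 in the
    first column and ones on the supradiagonal, V^0 = F(0) + g E and
    V^1 = F(1) + g E being the velocities at reset and threshold.  The
    product must reproduce the diagonal-Lambda block structure; any
    off-diagonal contamination above 1e-8 is reported as a bookkeeping
    error.
    """
    pulse = config.resolved_pulse
    N = config.N
    L = pulse.order_L
    T, vb = sync_orbit(config)
    flow = FlowMap(config.field, config.g, pulse)

    XT, D, b, Xdot = flow.propagate_with_partials([0.0], vb, T)
    D, bvec = float(D[0]), b[0]
    Ebar = float(vb[0])
    V1 = float(config.field.evaluate(1.0)) + config.g * Ebar
    V0 = float(config.field.evaluate(0.0)) + config.g * Ebar
    if abs(float(XT[0]) - 1.0) > 1e-9:
        raise RuntimeError("synchronous orbit does not reach threshold")

    dim = (N - 1) + L
    # -- first step: finite duration T --------------------------------
    tau1 = np.zeros(dim)
    tau1[0] = -D / V1
    tau1[N - 1:] = -bvec / V1
    B1 = np.zeros((dim, dim))
    for j in range(1, N):
        row = j - 1
        if j <= N - 2:
            B1[row, j] = D
        B1[row, N - 1:] += bvec
        B1[row, :] += V1 * tau1            # every non-fired neuron sits at X = 1
    Pt = pulse.propagator(T)
    v_pre = Pt @ vb                        # field just before the first crossing
    B1[N - 1:, N - 1:] += Pt
    B1[N - 1:, :] += np.outer(pulse.companion @ v_pre, tau1)

    # -- steps n = 2..N: zero length ----------------------------------
    M = B1
    jump = pulse.jump(N)
    for n in range(2, N + 1):
        G = np.zeros((dim, dim))
        for j in range(1, N):
            row = j - 1
            if j <= N - 2:
                G[row, j] = 1.0
            Vj = V1 if j <= N - n else V0   # reset neurons occupy the tail labels
            G[row, 0] += -Vj / V1
        G[N - 1:, N - 1:] += np.eye(L)
        v_now = v_pre + (n - 1) * jump      # field advances in K/N increments
        G[N - 1:, 0] += -(pulse.companion @ v_now) / V1
        M = G @ M

    # -- structure check and extraction -------------------------------
    pot = M[:N - 1, :N - 1]
    off = pot - np.diag(np.diag(pot))
    if np.max(np.abs(off)) > 1e-8:
        raise RuntimeError(
            f"synchronous product lost its diagonal structure "
            f"(off-diagonal {np.max(np.abs(off)):.2e}); bookkeeping bug")
    if np.max(np.abs(M[:N - 1, N - 1:])) > 1e-8:
        raise RuntimeError("potential block leaks into the field sector")
    diag = np.diag(pot)
    return SyncStabilityResult(
        config=config, period_T=T, field_v=vb,
        Lambda_jj=float(np.mean(diag)),
        Lambda_spread=float(np.max(diag) - np.min(diag)),
        field_multipliers=np.linalg.eigvals(M[N - 1:, N - 1:]),
        matrix=M,
    )


def evaporation_exponent(config: NetworkConfig, side: str,
                         delta: float = 2e-6, extrapolate: bool = True) -> float:
    """One-sided evaporation exponent of a probe neuron.

    The probe is displaced in firing time by -delta (side "+", probe
    ahead of the cluster) or +delta (side "-", probe behind), reset at
    its own firing and evolved through one full cluster period in the
    frozen periodic mean field, including the field jumps at the
    cluster's firing times.  Lambda_e = ln(Delta'/Delta)/T from the
    drift of the firing-time offset.  For pulses with a continuous E
    (alpha-pulses) the two sides agree and equal ln(Lambda_jj)/T; for
    discontinuous pulses (exponential) the probe ahead misses the field
    jump that the probe behind receives, and the two sides differ.
    """
    if side not in ("+", "-"):
        raise ValueError("side must be '+' or '-'")
    if extrapolate:
        # the crossing-time map has one-sided curvature: Richardson in delta
        l1 = evaporation_exponent(config, side, delta, extrapolate=False)
        l2 = evaporation_exponent(config, side, delta / 2.0, extrapolate=False)
        return 2.0 * l2 - l1
    pulse = config.resolved_pulse
    T, vb = sync_orbit(config)
    t0 = -delta if side == "+" else delta

    def rhs_factory(k):
        # within [kT, (k+1)T) the field is the smooth free decay from vb
        def rhs(t, x):
            E = float(pulse.E_row(t - k * T) @ vb)
            return np.asarray(config.field.evaluate(x), float) + config.g * E
        return rhs

    def hit(t, x):
        return x[0] - 1.0
    hit.terminal = True
    hit.direction = 1.0

    # integrate segment by segment between cluster firing times so the
    # field jumps at kT never fall inside an integration step
    x = 0.0
    t = t0
    t_cross = None
    k0 = int(math.floor(t0 / T + 1e-12))
    for k in range(k0, k0 + 3):
        t_end = (k + 1) * T
        if t >= t_end:
            continue
        sol = solve_ivp(rhs_factory(k), (t, t_end), [x], method="DOP853",
                        rtol=1e-13, atol=1e-15, max_step=T / 4.0, events=hit)
        if not sol.success:
            raise RuntimeError(f"probe integration failed: {sol.message}")
        if len(sol.t_events[0]):
            t_cross = float(sol.t_events[0][0])
            break
        x, t = float(sol.y[0, -1]), t_end
    if t_cross is None:
        raise RuntimeError("probe neuron did not reach threshold within one period")
    d_new = t_cross - T
    if d_new * t0 <= 0.0 or abs(d_new) > 0.95 * T:
        raise RuntimeError("probe lost the cluster by a full cycle")
    # For discontinuous pulses a probe behind an inhibitory cluster can be
    # pushed back across threshold by the field jump and escape by a finite
    # time offset; the log-rate is then delta-dependent but its (positive)
    # sign is the robust statement of one-sided instability.
    return math.log(d_new / t0) / T
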