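"""Fixed-step simulation and Lyapunov spectra of the periodically forced
network.

With a common drive A cos(phi), phi' = omega = 2 pi / T_a, written in
autonomous form, the network is integrated with a fourth-order
Runge-Kutta scheme at fixed dt.  Spike times must be located precisely
despite the quasi-periodic modulation of the interspike intervals, so
threshold crossings use the Henon trick: when X^1 overshoots, the step
is retracted and a single Runge-Kutta step is taken with X^1 as the
independent variable (step 1 - X^1), landing exactly on the threshold.

The Lyapunov spectrum is obtained by propagating a full orthonormal
tangent frame with the linearized equations

    x^j' = F'(X^j) x^j + g eps - A sin(phi) dphi,
    eps' = p - alpha eps,  p' = -alpha p,  dphi' = 0,

re-orthonormalized at every spike.  At a spike the tangent vectors
receive the exact event correction (saltation): with tau = -x^1/V^1,
the reset neuron's perturbation becomes V^0 tau and the field rows gain
the jump-size derivatives (alpha^2/N, -alpha^3/N) tau; labels roll as
in the event-driven map.  The delta-phi direction and the flow
direction are neutral, so two exponents vanish; the alpha-pulse field
contributes a strongly negative pair near -alpha.

Only alpha-pulses (L = 2) are supported here, matching the smooth-pulse
setting in which the forced scaling laws are studied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .config import NetworkConfig
from .event_driven import splay_fixed_point

__all__ = ["LyapunovResult", "simulate_forced", "lyapunov_spectrum",
           "initial_state", "default_dt"]

# velocity-field codes for the jitted kernel (catalog order)
_FIELD_CODES = {"F0": 0, "F1": 1, "F2": 2, "F3": 3, "F4": 4, "F5": 5,
                "F6": 6, "F7": 7}


@njit(cache=True)
def _F(code, a, x):
    if code == 0:
        return a - x
    if code == 1:
        return a - x * (x - 0.7)
    if code == 2:
        return a - 0.25 * np.sin(np.pi * x)
    if code == 3:
        return a + x * (x - 1.0)
    if code == 4:
        return a - 0.25 * np.sin(np.pi * x) * np.cos(np.pi * x) ** 2
    if code == 5:
        return a - 0.25 * np.sin(2 * np.pi * x) * np.cos(2 * np.pi * x) ** 2
    if code == 6:
        return a - 0.25 * np.sin(2 * np.pi * x) * np.exp(np.cos(2 * np.pi * x))
    return a - 1.0 + np.exp(2.0 * np.sin(2 * np.pi * x))


@njit(cache=True)
def _Fp(code, a, x):
    if code == 0:
        return -1.0
    if code == 1:
        return 0.7 - 2.0 * x
    if code == 2:
        return -0.25 * np.pi * np.cos(np.pi * x)
    if code == 3:
        return 2.0 * x - 1.0
    if code == 4:
        return -0.25 * np.pi * (np.cos(np.pi * x) ** 3
                                - 2.0 * np.sin(np.pi * x) ** 2 * np.cos(np.pi * x))
    if code == 5:
        return -0.5 * np.pi * (np.cos(2 * np.pi * x) ** 3
                               - 2.0 * np.sin(2 * np.pi * x) ** 2 * np.cos(2 * np.pi * x))
    if code == 6:
        e = np.exp(np.cos(2 * np.pi * x))
        return -0.5 * np.pi * e * (np.cos(2 * np.pi * x) - np.sin(2 * np.pi * x) ** 2)
    return 4.0 * np.pi * np.cos(2 * np.pi * x) * np.exp(2.0 * np.sin(2 * np.pi * x))


@njit(cache=True)
def _rhs(Y, dY, fp_buf, code, a, g, alpha, A, omega, N, henon):
    """Derivatives of Y: row 0 is the augmented state (X[0..N-1], E, P,
    phi, t), rows 1..M are tangent vectors (last slot unused).

    henon=True makes X^1 the independent variable (all rates divided by
    Xdot^1, X^1's own rate set to one).
    """
    M1 = Y.shape[0]
    E = Y[0, N]
    P = Y[0, N + 1]
    phi = Y[0, N + 2]
    drive = g * E + A * np.cos(phi)
    for i in range(N):
        dY[0, i] = _F(code, a, Y[0, i]) + drive
        fp_buf[i] = _Fp(code, a, Y[0, i])
    dY[0, N] = P - alpha * E
    dY[0, N + 1] = -alpha * P
    dY[0, N + 2] = omega
    dY[0, N + 3] = 1.0
    Asin = A * np.sin(phi)
    for m in range(1, M1):
        wE = Y[m, N]
        wP = Y[m, N + 1]
        forc = g * wE - Asin * Y[m, N + 2]
        for i in range(N):
            dY[m, i] = fp_buf[i] * Y[m, i] + forc
        dY[m, N] = wP - alpha * wE
        dY[m, N + 1] = -alpha * wP
        dY[m, N + 2] = 0.0
        dY[m, N + 3] = 0.0
    if henon:
        inv = 1.0 / dY[0, 0]
        for m in range(M1):
            for i in range(N + 4):
                dY[m, i] *= inv
        dY[0, 0] = 1.0


@njit(cache=True)
def _rk4_inplace(Y, h, k1, k2, k3, k4, Yt, fp_buf,
                 code, a, g, alpha, A, omega, N, henon):
    M1, D = Y.shape
    _rhs(Y, k1, fp_buf, code, a, g, alpha, A, omega, N, henon)
    for m in range(M1):
        for i in range(D):
            Yt[m, i] = Y[m, i] + 0.5 * h * k1[m, i]
    _rhs(Yt, k2, fp_buf, code, a, g, alpha, A, omega, N, henon)
    for m in range(M1):
        for i in range(D):
            Yt[m, i] = Y[m, i] + 0.5 * h * k2[m, i]
    _rhs(Yt, k3, fp_buf, code, a, g, alpha, A, omega, N, henon)
    for m in range(M1):
        for i in range(D):
            Yt[m, i] = Y[m, i] + h * k3[m, i]
    _rhs(Yt, k4, fp_buf, code, a, g, alpha, A, omega, N, henon)
    c = h / 6.0
    for m in range(M1):
        for i in range(D):
            Y[m, i] += c * (k1[m, i] + 2.0 * k2[m, i] + 2.0 * k3[m, i] + k4[m, i])


@njit(cache=True)
def _apply_event(Y, code, a, g, alpha, A, omega, N):
    """Reset/relabel/field-jump at X^1 = 1, with tangent saltation."""
    M1 = Y.shape[0]
    E = Y[0, N]
    phi = Y[0, N + 2]
    drive = g * E + A * np.cos(phi)
    v1 = _F(code, a, 1.0) + drive
    v0 = _F(code, a, 0.0) + drive
    jE = alpha * alpha / N
    jP = -alpha * alpha * alpha / N
    for m in range(1, M1):
        # fixed-time (not section) comparison: w+ = Dg w - (f+ - Dg f-) tau
        # with tau = -w_x1 / v1 the crossing-time shift of this vector
        tau = -Y[m, 0] / v1
        w0 = -v0 * tau
        for i in range(N - 1):
            Y[m, i] = Y[m, i + 1]
        Y[m, N - 1] = w0
        Y[m, N] -= jE * tau
        Y[m, N + 1] -= jP * tau
    for i in range(N - 1):
        Y[0, i] = Y[0, i + 1]
    Y[0, N - 1] = 0.0
    Y[0, N + 1] += alpha * alpha / N


@njit(cache=True)
def _run(Y, code, a, g, alpha, A, omega, dt, n_trans, n_meas, N,
         record_E, E_stride):
    """Main loop.  Y rows: state + M tangent vectors.  Returns
    (log-sums, measured time, spike times (capped), E samples)."""
    M1 = Y.shape[0]
    M = M1 - 1
    D = Y.shape[1]
    k1 = np.empty_like(Y)
    k2 = np.empty_like(Y)
    k3 = np.empty_like(Y)
    k4 = np.empty_like(Y)
    Yt = np.empty_like(Y)
    Yp = np.empty_like(Y)
    fp_buf = np.empty(N)
    sumlog = np.zeros(max(M, 1))
    n_spikes = 0
    t_start = 0.0
    max_keep = min(n_meas, 20000)
    spike_times = np.empty(max_keep)
    kept = 0
    nE = 0
    E_samples = np.empty((max(record_E, 1), 2))
    step = 0
    total = n_trans + n_meas
    while n_spikes < total:
        Yp[:, :] = Y
        _rk4_inplace(Y, dt, k1, k2, k3, k4, Yt, fp_buf,
                     code, a, g, alpha, A, omega, N, False)
        step += 1
        if record_E > 0 and nE < record_E and step % E_stride == 0:
            E_samples[nE, 0] = Y[0, N + 3]
            E_samples[nE, 1] = Y[0, N]
            nE += 1
        crossings = 0
        while Y[0, 0] > 1.0:
            if crossings == 0:
                Y[:, :] = Yp  # retract the full step
            h = 1.0 - Y[0, 0]
            _rk4_inplace(Y, h, k1, k2, k3, k4, Yt, fp_buf,
                         code, a, g, alpha, A, omega, N, True)
            Y[0, 0] = 1.0
            _apply_event(Y, code, a, g, alpha, A, omega, N)
            n_spikes += 1
            crossings += 1
            if M > 0:
                W = np.ascontiguousarray(Y[1:, :N + 3].T)
                Q, R = np.linalg.qr(W)
                for m in range(M):
                    r = R[m, m]
                    if r < 0.0:
                        r = -r
                        for i in range(N + 3):
                            Q[i, m] = -Q[i, m]
                    if n_spikes > n_trans:
                        sumlog[m] += np.log(r)
                for m in range(M):
                    for i in range(N + 3):
                        Y[1 + m, i] = Q[i, m]
            if n_spikes == n_trans:
                t_start = Y[0, N + 3]
            if n_spikes > n_trans and kept < max_keep:
                spike_times[kept] = Y[0, N + 3]
                kept += 1
            if n_spikes >= total:
                break
    t_meas = Y[0, N + 3] - t_start
    return sumlog, t_meas, spike_times[:kept], E_samples[:nE], Y


@dataclass
class LyapunovResult:
    """Time-averaged expansion rates of the forced network.

    exponents are sorted in decreasing order; the flow direction and the
    forcing-phase direction contribute (near-)zeros, the alpha-pulse
    field a pair close to -alpha.
    """

    config: NetworkConfig
    exponents: np.ndarray
    n_spikes_transient: int
    n_spikes_measured: int
    step_dt: float
    mean_isi: float


def _kernel_params(config: NetworkConfig):
    if config.field.name not in _FIELD_CODES:
        raise ValueError("forced simulations support the catalog fields F0..F7")
    pulse = config.resolved_pulse
    if pulse.order_L != 2 or pulse.poles[0] != pulse.poles[1]:
        raise ValueError("forced simulations are implemented for alpha-pulses")
    return _FIELD_CODES[config.field.name], config.field.param_a, pulse.poles[0]


def _unforced(config: NetworkConfig) -> NetworkConfig:
    return NetworkConfig(N=config.N, g=config.g, field=config.field,
                         pulse=config.pulse)


def initial_state(config: NetworkConfig, seed: int = 0,
                  jitter: float = 1e-6) -> np.ndarray:
    """Splay fixed point of the unforced network plus uniform jitter.

    Returns the augmented state (X[0..N-1], E, P, phi, t); the reset
    slot X^N = 0 gets no jitter so labels stay ordered.
    """
    fp = splay_fixed_point(_unforced(config))
    rng = np.random.default_rng(seed)
    X = np.concatenate([fp.potentials_X, [0.0]])
    X[:-1] = np.sort(X[:-1] + jitter * rng.uniform(-1, 1, config.N - 1))[::-1]
    return np.concatenate([X, [fp.E_tilde, fp.P_tilde, 0.0, 0.0]])


def default_dt(config: NetworkConfig, dt_factor: int = 20) -> float:
    """Step resolving both the interspike interval and the forcing period."""
    fp_T = splay_fixed_point(_unforced(config)).interspike_T
    Ta = config.forcing_Ta if config.forcing_Ta else np.inf
    return min(fp_T, Ta) / dt_factor


def simulate_forced(config: NetworkConfig, n_spikes: int, dt: float | None = None,
                    seed: int = 0, record_E: int = 0):
    """Forced trajectory only (no tangent): returns (spike times,
    E(t) samples as an (n, 2) array of (t, E))."""
    code, a, alpha = _kernel_params(config)
    if dt is None:
        dt = default_dt(config)
    Y = initial_state(config, seed)[None, :].copy()
    stride = max(1, int(round((config.forcing_Ta or 1.0) / dt / 64)))
    _, _, spikes, E_samples, _ = _run(Y, code, a, config.g, alpha,
                                      config.forcing_A, config.omega,
                                      dt, 0, n_spikes, config.N, record_E, stride)
    return spikes, E_samples


def lyapunov_spectrum(config: NetworkConfig, n_spikes: int | None = None,
                      dt: float | None = None, seed: int = 0,
                      n_transient: int | None = None) -> LyapunovResult:
    """Full Lyapunov spectrum by tangent-frame propagation.

    Defaults: transient 200 N spikes, measurement 2000 N spikes, step
    dt = min(T, T_a)/20 with T the unforced interspike interval.
    """
    code, a, alpha = _kernel_params(config)
    N = config.N
    if dt is None:
        dt = default_dt(config)
    n_transient = 200 * N if n_transient is None else n_transient
    n_spikes = 2000 * N if n_spikes is None else n_spikes
    D = N + 3
    Y = np.zeros((D + 1, N + 4))
    Y[0] = initial_state(config, seed)
    Y[1:, :D] = np.eye(D)
    sumlog, t_meas, spikes, _, _ = _run(Y, code, a, config.g, alpha,
                                        config.forcing_A, config.omega,
                                        dt, n_transient, n_spikes, N, 0, 1)
    lam = np.sort(sumlog / t_meas)[::-1]
    isi = float(np.mean(np.diff(spikes))) if len(spikes) > 2 else float("nan")
    return LyapunovResult(config=config, exponents=lam,
                          n_spikes_transient=n_transient,
                          n_spikes_measured=n_spikes, step_dt=dt,
                          mean_isi=isi)
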