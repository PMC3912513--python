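import numpy as np
import pytest

from pulsestab.config import NetworkConfig
from pulsestab.forced import (default_dt, initial_state, lyapunov_spectrum,
                              simulate_forced)
from pulsestab.pulses import PulseModel
from pulsestab.splay_floquet import floquet_spectrum_splay


@pytest.fixture(scope="module")
def stable_cfg(lif, alpha3):
    # excitatory coupling: the unforced splay state is attracting
    return NetworkConfig(N=10, g=0.3, field=lif, pulse=alpha3,
                         forcing_A=0.1, forcing_Ta=2.0)


def test_unforced_spike_times_equidistant(stable_cfg, lif, alpha3):
    """A=0 from the splay point: spike times stay equidistant."""
    cfg = NetworkConfig(N=10, g=0.3, field=lif, pulse=alpha3,
                        forcing_A=0.0, forcing_Ta=2.0)
    spikes, _ = simulate_forced(cfg, n_spikes=400, seed=1)
    isis = np.diff(spikes[100:])
    # spread reflects only the 1e-6 preparation jitter of the splay point
    # (absolute ~1e-6 on an interval of ~0.1), far below any forcing
    # -induced modulation
    assert np.std(isis) < 3e-5 * np.mean(isis)


def test_unforced_exponents_reproduce_floquet(stable_cfg, lif, alpha3):
    """A=0: the Lyapunov spectrum equals the splay Floquet exponents,
    plus two exact neutral directions (flow and forcing phase)."""
    cfg = NetworkConfig(N=10, g=0.3, field=lif, pulse=alpha3,
                        forcing_A=0.0, forcing_Ta=2.0)
    r = lyapunov_spectrum(cfg, n_spikes=20000, n_transient=2000, seed=1)
    fl = floquet_spectrum_splay(NetworkConfig(N=10, g=0.3, field=lif,
                                              pulse=alpha3))
    lam_f = np.sort(fl.lam)[::-1]
    lam_l = r.exponents
    # two near-zero neutral exponents present
    assert np.sum(np.abs(lam_l) < 1e-3) >= 2
    # remaining exponents match the Floquet spectrum (5% of spectral scale)
    rest = np.sort(np.concatenate([lam_l[np.abs(lam_l) >= 1e-3]]))[::-1]
    scale = np.max(np.abs(lam_f))
    matched = lam_f[:len(rest)]
    assert np.mean(np.abs(rest - matched)) < 0.05 * scale
    # the field pair is reproduced almost exactly
    assert np.allclose(np.sort(rest)[:2], np.sort(lam_f)[:2], rtol=1e-3)


def test_forcing_modulates_mean_field_periodically(stable_cfg):
    """A=0.1: E(t) is modulated with the forcing period T_a."""
    _, E = simulate_forced(stable_cfg, n_spikes=4000, seed=1, record_E=2000)
    t, Ev = E[500:, 0], E[500:, 1]
    Ta = stable_cfg.forcing_Ta
    # correlate E with the two quadratures of the drive
    c1 = np.mean((Ev - Ev.mean()) * np.cos(2 * np.pi * t / Ta))
    c2 = np.mean((Ev - Ev.mean()) * np.sin(2 * np.pi * t / Ta))
    power = np.hypot(c1, c2)
    assert power > 10 * np.abs(np.mean(
        (Ev - Ev.mean()) * np.cos(2 * np.pi * t / (0.377 * Ta))))


def test_no_locking_of_single_neuron_frequency(stable_cfg):
    """Zero-average forcing shifts the mean interspike interval slightly
    but does not lock the neuron frequency to the drive: the rotation
    number N*ISI/T_a stays away from low-order rationals."""
    spikes, _ = simulate_forced(stable_cfg, n_spikes=6000, seed=1)
    isi = np.mean(np.diff(spikes[1000:]))
    rho = stable_cfg.N * isi / stable_cfg.forcing_Ta  # neuron period / T_a
    best = min(abs(rho - p / q)
               for q in range(1, 9) for p in range(1, int(8 * q)))
    assert best > 1e-3


def test_phase_direction_is_neutral(stable_cfg):
    r = lyapunov_spectrum(stable_cfg, n_spikes=4000, n_transient=500, seed=1)
    assert np.min(np.abs(r.exponents)) < 1e-8


def test_step_halving_stability(stable_cfg):
    """Exponents move by < 1% of the spectral scale when dt -> dt/2."""
    dt = default_dt(stable_cfg)
    r1 = lyapunov_spectrum(stable_cfg, n_spikes=6000, n_transient=1000,
                           dt=dt, seed=1)
    r2 = lyapunov_spectrum(stable_cfg, n_spikes=6000, n_transient=1000,
                           dt=dt / 2, seed=1)
    scale = np.max(np.abs(r1.exponents))
    assert np.max(np.abs(r1.exponents - r2.exponents)) < 0.01 * scale


def test_tangent_matches_two_trajectory_separation(stable_cfg):
    """The tangent propagation (with its event corrections) reproduces
    the finite-difference state separation of two nearby forced
    trajectories, compared at a common time after 100 spikes."""
    from pulsestab.forced import _F, _kernel_params, _run
    cfg = stable_cfg
    N = cfg.N
    code, a, alpha = _kernel_params(cfg)
    dt = default_dt(cfg)
    n_spk = 100
    s0 = initial_state(cfg, seed=3)
    direction = np.zeros(N + 3)
    direction[: N - 1] = np.linspace(1.0, 0.5, N - 1)
    direction[N: N + 2] = (0.3, -0.2)
    direction /= np.linalg.norm(direction)

    eps = 1e-8
    ends, spikes = [], []
    for s in (s0, s0 + eps * np.concatenate([direction, [0.0]])):
        Y = s[None, :].copy()
        _, _, spk, _, Yf = _run(Y, code, a, cfg.g, alpha, cfg.forcing_A,
                                cfg.omega, dt, 0, n_spk, N, 0, 1)
        ends.append(Yf[0].copy())
        spikes.append(spk)

    # both runs stop at their own 100th spike; transporting the perturbed
    # end state back by the spike-time offset along the flow gives the
    # fixed-time difference that the tangent vector represents
    dt_end = ends[1][N + 3] - ends[0][N + 3]
    sref = ends[0]
    f = np.empty(N + 3)
    drive = cfg.g * sref[N] + cfg.forcing_A * np.cos(sref[N + 2])
    for i in range(N):
        f[i] = _F(code, a, sref[i]) + drive
    f[N] = sref[N + 1] - alpha * sref[N]
    f[N + 1] = -alpha * sref[N + 1]
    f[N + 2] = cfg.omega
    w_fd = (ends[1][: N + 3] - ends[0][: N + 3]) / eps - f * (dt_end / eps)

    # tangent run seeded with the same direction: final direction times
    # accumulated growth (single column, QR is a pure normalization)
    Y = np.zeros((2, N + 4))
    Y[0] = s0
    Y[1, : N + 3] = direction
    sumlog, _, _, _, Yf = _run(Y, code, a, cfg.g, alpha, cfg.forcing_A,
                               cfg.omega, dt, 0, n_spk, N, 0, 1)
    w_tan = Yf[1, : N + 3] * np.exp(sumlog[0])
    assert np.linalg.norm(w_fd - w_tan) < 1e-4 * np.linalg.norm(w_tan)


def test_forced_requires_alpha_pulses(lif):
    cfg = NetworkConfig(N=6, g=0.3, field=lif,
                        pulse=PulseModel.exponential(3.0),
                        forcing_A=0.1, forcing_Ta=2.0)
    with pytest.raises(ValueError, match="alpha-pulses"):
        lyapunov_spectrum(cfg, n_spikes=10)
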