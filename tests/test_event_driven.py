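import numpy as np
import pytest

from pulsestab.config import NetworkConfig
from pulsestab.event_driven import (DeltaFlow, FlowMap, NetworkState,
                                    event_step, splay_fixed_point)
from pulsestab.fields import field_catalog
from pulsestab.pulses import PulseModel


# ---------------------------------------------------------------- flow map
def test_flow_identity_at_zero_duration(lif, alpha3):
    fl = FlowMap(lif, -0.4, alpha3)
    v = alpha3.fixed_point(0.1, 20)
    X, D, b, _ = fl.propagate_with_partials([0.3, 0.7], v, 0.0)
    assert np.allclose(X, [0.3, 0.7])
    assert np.allclose(D, 1.0)
    assert np.allclose(b, 0.0)


def test_lif_closed_form_vs_numeric(lif, alpha3):
    """The exact linear-ODE propagator and the integrator agree to 1e-10."""
    rng = np.random.default_rng(7)
    fl_cf = FlowMap(lif, -0.4, alpha3, closed_form=True)
    fl_num = FlowMap(lif, -0.4, alpha3)
    for _ in range(5):
        x0 = rng.uniform(0, 0.9)
        v = rng.uniform(0.1, 1.0, 2)
        T = rng.uniform(0.01, 0.5)
        assert fl_cf.propagate(x0, v, T) == pytest.approx(
            fl_num.propagate(x0, v, T), abs=1e-10)
    with pytest.raises(ValueError):
        FlowMap(field_catalog("F1", 1.3), 0.0, alpha3, closed_form=True)


def test_variational_partials_match_finite_differences(f1, alpha3):
    fl = FlowMap(f1, -0.4, alpha3)
    v = alpha3.fixed_point(0.05, 30)
    x0, T, h = 0.42, 0.12, 1e-7
    XT, D, b, Xdot = fl.propagate_with_partials([x0], v, T)
    assert D[0] == pytest.approx(
        (fl.propagate(x0 + h, v, T) - fl.propagate(x0 - h, v, T)) / (2 * h),
        rel=1e-6)
    for m in range(2):
        dv = np.zeros(2)
        dv[m] = h
        fd = (fl.propagate(x0, v + dv, T) - fl.propagate(x0, v - dv, T)) / (2 * h)
        assert b[0, m] == pytest.approx(fd, rel=1e-6, abs=1e-9)
    # duration derivative is the end velocity
    fd_T = (fl.propagate(x0, v, T + h) - fl.propagate(x0, v, T - h)) / (2 * h)
    assert Xdot[0] == pytest.approx(fd_T, rel=1e-7)


def test_variational_D_is_exp_integral_of_Fprime_at_g0(f1, alpha3):
    """For g=0 the X-partial equals exp(int F'(X(t)) dt) = F(X_T)/F(X_0)
    (autonomous 1-D flow identity)."""
    fl = FlowMap(f1, 0.0, alpha3)
    v = np.zeros(2)
    XT, D, _, _ = fl.propagate_with_partials([0.25], v, 0.3)
    assert D[0] == pytest.approx(
        float(f1.evaluate(XT[0])) / float(f1.evaluate(0.25)), rel=1e-10)


# ------------------------------------------------------------- event step
def test_uncoupled_lif_interspike_closed_form(lif, alpha3):
    """g=0: T = ln((a - X^1)/(a - 1)) for the LIF field."""
    a = 1.3
    cfg = NetworkConfig(N=5, g=0.0, field=lif, pulse=alpha3)
    X = np.array([0.8, 0.5, 0.3, 0.1])
    st = NetworkState(X, alpha3.fixed_point(0.3, 5))
    _, T = event_step(st, cfg)
    assert T == pytest.approx(np.log((a - 0.8) / (a - 1.0)), abs=1e-11)


def test_event_step_near_threshold(lif, alpha3):
    cfg = NetworkConfig(N=4, g=0.0, field=lif, pulse=alpha3)
    st = NetworkState(np.array([1.0 - 1e-14, 0.4, 0.2]),
                      alpha3.fixed_point(0.3, 4))
    new, T = event_step(st, cfg)
    assert 0.0 <= T < 1e-12
    assert np.all(np.diff(new.potentials) <= 1e-12)


def test_order_preservation_under_iteration(f1, alpha3):
    """Neurons rotate without overtaking: ordering survives arbitrary
    iteration from random ordered initial conditions."""
    rng = np.random.default_rng(3)
    cfg = NetworkConfig(N=6, g=-0.4, field=f1, pulse=alpha3)
    X = np.sort(rng.uniform(0, 0.99, 5))[::-1]
    st = NetworkState(X, alpha3.fixed_point(0.2, 6))
    for _ in range(1000):
        st, T = event_step(st, cfg)
        assert T > 0
        assert np.all(np.diff(st.potentials) <= 1e-10)
        assert np.all(st.potentials >= -1e-9) and np.all(st.potentials <= 1 + 1e-9)


# ------------------------------------------------------- splay fixed point
def test_splay_g0_period_is_free_period(lif, alpha3):
    cfg = NetworkConfig(N=10, g=0.0, field=lif, pulse=alpha3)
    fp = splay_fixed_point(cfg)
    assert fp.period_T0 == pytest.approx(np.log(1.3 / 0.3), abs=1e-10)


def test_splay_fixed_point_self_consistency(f1, alpha3):
    """One event step maps the splay point to itself (after the label
    shift) componentwise, and repeated stepping does not drift."""
    cfg = NetworkConfig(N=20, g=-0.4, field=f1, pulse=alpha3)
    fp = splay_fixed_point(cfg)
    st = fp.state()
    for _ in range(10):
        st, T = event_step(st, cfg)
        assert T == pytest.approx(fp.interspike_T, abs=1e-9)
    assert np.max(np.abs(st.potentials - fp.potentials_X)) < 1e-8
    assert np.max(np.abs(st.field_v - fp.field_v)) < 1e-8


def test_splay_field_relations(f1, alpha3):
    """Fixed-point field values satisfy the one-interval periodicity with
    the end-of-interval jump: P~ = (alpha^2/N)/(1 - e^{-alpha T})."""
    cfg = NetworkConfig(N=30, g=-0.4, field=f1, pulse=alpha3)
    fp = splay_fixed_point(cfg)
    T = fp.interspike_T
    assert fp.P_tilde == pytest.approx(
        (9.0 / 30) / (1.0 - np.exp(-3.0 * T)), rel=1e-10)
    Et = np.exp(-3 * T) * (fp.E_tilde + T * fp.P_tilde)
    assert Et == pytest.approx(fp.E_tilde, rel=1e-10)


def test_splay_simulation_oracle(lif, alpha3):
    """Forward event-driven simulation from a perturbed splay produces the
    same mean interspike interval as the fixed-point solver."""
    cfg = NetworkConfig(N=50, g=-0.4, field=lif, pulse=alpha3)
    fp = splay_fixed_point(cfg)
    rng = np.random.default_rng(11)
    X = np.sort(fp.potentials_X + 1e-8 * rng.uniform(-1, 1, 49))[::-1]
    st = NetworkState(X, fp.field_v.copy())
    Ts = []
    for _ in range(300):
        st, T = event_step(st, cfg)
        Ts.append(T)
    assert np.mean(Ts[-150:]) == pytest.approx(fp.interspike_T, abs=1e-8)


# ------------------------------------------------------------ delta pulses
def test_delta_flow_matches_quadrature(lif):
    df = DeltaFlow(lif)
    # time to threshold from 0 equals the free period
    assert df.time_to_threshold(0.0) == pytest.approx(np.log(1.3 / 0.3), abs=1e-10)
    # advance solves a - X' = (a - X) e^{-T}
    x, T = 0.2, 0.4
    assert df.advance(x, T) == pytest.approx(1.3 - (1.3 - 0.2) * np.exp(-0.4),
                                             abs=1e-10)


def test_delta_splay_inhibitory_is_stable(lif):
    """delta-pulse LIF splay with inhibition contracts perturbations
    (forward-simulation check of the classical stability result)."""
    cfg = NetworkConfig(N=10, g=-0.4, field=lif, pulse=PulseModel.delta())
    fp = splay_fixed_point(cfg)
    rng = np.random.default_rng(5)
    X = np.sort(fp.potentials_X + 1e-5 * rng.uniform(-1, 1, 9))[::-1]
    st = NetworkState(X, np.zeros(0))
    d0 = np.max(np.abs(st.potentials - fp.potentials_X))
    for _ in range(200):
        st, _ = event_step(st, cfg)
    d1 = np.max(np.abs(st.potentials - fp.potentials_X))
    assert d1 < 0.2 * d0


def test_beta_pulse_ratio_R_is_N_independent(f1):
    """alpha = beta N keeps R = N/(T0 alpha) finite and N-independent."""
    pulse = PulseModel.beta_pulse(0.03)
    Rs = []
    for N in (50, 100, 200):
        cfg = NetworkConfig(N=N, g=-0.4, field=f1, pulse=pulse)
        Rs.append(splay_fixed_point(cfg).ratio_R)
    assert np.ptp(Rs) / np.mean(Rs) < 0.01
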