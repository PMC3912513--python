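import numpy as np
import pytest

from pulsestab.fields import constant_field, field_catalog
from pulsestab.meanfield import (MeanField, asymptotic_real_part,
                                 lif_delta_limit, meanfield_period,
                                 scaling_exponent_q)
from pulsestab.pulses import PulseModel


@pytest.fixture(scope="module")
def mf_lif(lif, alpha3):
    return MeanField(lif, alpha3, -0.4)


def test_selfconsistent_period_normalizes_prc(f1):
    """T0 solving int dX/(g + T0 F) = 1 makes y(1) = 1 exactly and
    matches the large-N event-driven fixed point."""
    from pulsestab.config import NetworkConfig
    from pulsestab.event_driven import splay_fixed_point
    T0 = meanfield_period(f1, -0.4)
    fp = splay_fixed_point(NetworkConfig(N=400, g=-0.4, field=f1,
                                         pulse=PulseModel.alpha_pulse(3.0)))
    assert T0 == pytest.approx(fp.period_T0, rel=1e-6)


def test_constant_prc_spectrum_purely_imaginary(alpha3):
    """Constant G: the eigenvalues are the marginal values 2 pi i n / T0
    — no effective interaction among phases."""
    mf = MeanField(constant_field(1.0), alpha3, -0.3)
    for n in (1, 2, 5):
        lam = mf.eigenvalue_equation_root(n).eigenvalue
        assert abs(lam.real) < 1e-12
        assert lam.imag == pytest.approx(2 * np.pi * n / mf.T0, rel=1e-10)
        A, B = mf.fourier_prc(n)
        assert abs(A) < 1e-12 and abs(B) < 1e-12


def test_pole_sector_roots(lif, alpha3):
    """g=0: the L polynomial roots are the field poles -alpha_k."""
    mf = MeanField(lif, alpha3, 0.0)
    roots = mf.pole_sector_roots()
    # double root: numerical splitting is O(sqrt(eps))
    assert np.allclose(roots, -3.0, atol=1e-5)


def test_conjugate_symmetry(mf_lif):
    for n in (1, 4):
        lp = mf_lif.perturbative_eigenvalue(n).eigenvalue
        lm = mf_lif.perturbative_eigenvalue(-n).eigenvalue
        assert lm == pytest.approx(np.conj(lp), rel=1e-12)


def test_exact_root_matches_perturbative_to_second_order(lif, alpha3):
    """Halving g shrinks |exact - perturbative| at least four-fold."""
    d = {}
    for g in (-0.2, -0.1):
        mf = MeanField(lif, alpha3, g)
        d[g] = abs(mf.eigenvalue_equation_root(4).eigenvalue
                   - mf.perturbative_eigenvalue(4).eigenvalue)
    assert d[-0.1] < d[-0.2] / 3.5


def test_lif_fourier_asymptotics(mf_lif):
    """Quadrature Fourier components converge to the endpoint closed
    forms as n grows (discontinuous F: B_n ~ 1/n dominates)."""
    rel_prev = np.inf
    for n in (16, 64, 256):
        Aq, Bq = mf_lif.fourier_prc(n)
        Aa, Ba = mf_lif.fourier_prc(n, "asymptotic")
        rel = abs(Bq / Ba - 1.0) + abs(Aq / Aa - 1.0)
        assert rel < rel_prev
        rel_prev = rel
    assert rel < 1e-4


def test_c0_field_fourier_decay(alpha3):
    """F(0)=F(1): the 1/n boundary term of B_n vanishes (for the mirror
    -symmetric catalog fields B_n is zero identically), while n^2 A_n
    approaches the endpoint-derivative bracket."""
    f2 = field_catalog("F2", 1.3)
    mf = MeanField(f2, alpha3, -0.4)
    _, Ba = mf.fourier_prc(1, "asymptotic")
    assert Ba == 0.0
    n_vals = (8, 32, 128)
    for n in n_vals:
        assert abs(mf.fourier_prc(n)[1]) < 1e-12
    Aa2 = mf.fourier_prc(128, "asymptotic")[0] * 128 ** 2
    assert mf.fourier_prc(128)[0] * 128 ** 2 == pytest.approx(Aa2, rel=1e-3)


def test_asymptotic_real_part_even_L(f1, alpha3, mf_lif):
    """Even L, discontinuous F: the closed form with K T0^L (-1)^{L/2}
    matches the first-order eigenvalue at large n."""
    T0 = meanfield_period(f1, -0.4)
    mf = MeanField(f1, alpha3, -0.4, T0=T0)
    for n in (32, 128):
        assert mf.perturbative_eigenvalue(n).eigenvalue.real == pytest.approx(
            asymptotic_real_part(f1, alpha3, -0.4, T0, n), rel=0.02)


def test_asymptotic_real_part_odd_L(f1):
    pe = PulseModel.exponential(3.0)
    mf = MeanField(f1, pe, -0.4)
    for n in (64, 256):
        assert mf.perturbative_eigenvalue(n).eigenvalue.real == pytest.approx(
            asymptotic_real_part(f1, pe, -0.4, mf.T0, n), rel=0.01)


def test_asymptotic_continuous_even_L_scaling(alpha3):
    """Continuous F with even L: eigenvalues fall off as n^{-(L+2)}."""
    f2 = field_catalog("F2", 1.3)
    mf = MeanField(f2, alpha3, -0.4)
    r8 = asymptotic_real_part(f2, alpha3, -0.4, mf.T0, 8, mf=mf)
    r16 = asymptotic_real_part(f2, alpha3, -0.4, mf.T0, 16, mf=mf)
    assert r8 / r16 == pytest.approx(16.0, rel=1e-6)
    assert mf.perturbative_eigenvalue(16).eigenvalue.real == pytest.approx(
        r16, rel=0.02)


def test_scaling_exponent_q():
    assert [scaling_exponent_q(L) for L in (1, 2, 3, 4)] == [2, 2, 4, 4]


def test_delta_pulse_modes_do_not_decay():
    with pytest.raises(ValueError):
        asymptotic_real_part(field_catalog("F0", 1.3), PulseModel.delta(),
                             -0.4, 1.5, 4)


def test_lif_delta_limit_values():
    a = 1.3
    T0_free = np.log(a / (a - 1.0))
    # uncoupled period: the limit is exactly marginal
    assert lif_delta_limit(a, T0_free) == pytest.approx(0.0, abs=1e-14)
    # inhibitory coupling lengthens T0: the limit becomes negative
    assert lif_delta_limit(a, 1.5 * T0_free) < 0.0
    with pytest.raises(ValueError):
        lif_delta_limit(0.9, 1.0)
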