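import numpy as np
import pytest

from conftest import finite_difference_jacobian
from pulsestab.config import NetworkConfig
from pulsestab.event_driven import splay_fixed_point
from pulsestab.pulses import PulseModel
from pulsestab.splay_floquet import (floquet_matrix_splay,
                                     floquet_spectrum_splay, sw_exponent)


@pytest.fixture(scope="module")
def f1_spectrum_N100(f1, alpha3):
    cfg = NetworkConfig(N=100, g=-0.4, field=f1, pulse=alpha3)
    return floquet_spectrum_splay(cfg)


@pytest.mark.parametrize("pulse_kind", ["alpha", "exp", "delta"])
def test_matrix_equals_finite_difference_jacobian(f1, lif, pulse_kind):
    """The analytically assembled one-step matrix agrees column-by-column
    with the brute-force Jacobian of the nonlinear event-driven map."""
    pulse = {"alpha": PulseModel.alpha_pulse(3.0),
             "exp": PulseModel.exponential(3.0),
             "delta": PulseModel.delta()}[pulse_kind]
    field = lif if pulse_kind == "delta" else f1
    cfg = NetworkConfig(N=6, g=-0.4, field=field, pulse=pulse)
    fp = splay_fixed_point(cfg)
    A = floquet_matrix_splay(fp, cfg)
    J = finite_difference_jacobian(cfg, fp.state().vector)
    assert np.max(np.abs(A - J)) < 1e-5


def test_determinant_is_product_of_multipliers(f1, alpha3):
    cfg = NetworkConfig(N=8, g=-0.4, field=f1, pulse=alpha3)
    A = floquet_matrix_splay(splay_fixed_point(cfg), cfg)
    mu = np.linalg.eigvals(A)
    assert np.linalg.det(A) == pytest.approx(np.prod(mu).real, rel=1e-8)


def test_g0_block_structure_and_marginality(f1, alpha3):
    """At g=0 the matrix decouples: the field block contributes the
    double multiplier e^{-alpha T}, the potential sector is marginal
    (|mu| = 1: neutral phase shifts of uncoupled oscillators), and the
    full-period map A^N has unit eigenvalues."""
    cfg = NetworkConfig(N=8, g=0.0, field=f1, pulse=alpha3)
    fp = splay_fixed_point(cfg)
    A = floquet_matrix_splay(fp, cfg)
    # g=0: the potentials do not feel the field (the reverse coupling —
    # field rows reacting to the spike time — persists at any g)
    assert np.max(np.abs(A[:7, 7:])) < 1e-12
    r = floquet_spectrum_splay(cfg, fp)
    assert np.max(np.abs(r.lam[~r.is_field])) < 1e-8
    assert np.allclose(r.multipliers[r.is_field],
                       np.exp(-3.0 * fp.interspike_T), atol=1e-9)
    muN = np.linalg.eigvals(np.linalg.matrix_power(A, 8))
    assert np.min(np.abs(muN - 1.0)) < 1e-6


def test_conjugate_symmetry_and_reconstruction(f1_spectrum_N100):
    """Non-real multipliers come in conjugate pairs and the wavenumber
    decomposition mu = e^{i phi} e^{T0 (lambda + i omega)/N} holds."""
    r = f1_spectrum_N100
    mu = r.multipliers
    complex_mu = mu[np.abs(mu.imag) > 1e-12]
    for m in complex_mu:
        assert np.min(np.abs(complex_mu - np.conj(m))) < 1e-9
    N, T0 = r.config.N, r.period_T0
    rebuilt = np.exp(1j * r.wavenumbers) * np.exp(T0 * (r.lam + 1j * r.omega) / N)
    assert np.max(np.abs(rebuilt - mu)) < 1e-9
    assert r.assignment_ok


def test_lw_branch_matches_meanfield_asymptotics(f1_spectrum_N100, f1, alpha3):
    """Finite-N long-wavelength exponents match the leading mean-field
    closed form within a few percent for 5 <= k <= N/10."""
    from pulsestab.meanfield import asymptotic_real_part, meanfield_period
    r = f1_spectrum_N100
    T0 = meanfield_period(f1, -0.4)
    k, lam = r.lw_modes(5, 10)
    for kk, ll in zip(k, lam):
        th = asymptotic_real_part(f1, alpha3, -0.4, T0, int(kk))
        assert ll == pytest.approx(th, rel=0.10)


def test_lw_branch_independent_of_N(f1, alpha3):
    """lambda_k for fixed small k changes by < 2% between N=100 and N=200."""
    r2 = floquet_spectrum_splay(NetworkConfig(N=200, g=-0.4, field=f1,
                                              pulse=alpha3))
    r1 = floquet_spectrum_splay(NetworkConfig(N=100, g=-0.4, field=f1,
                                              pulse=alpha3))
    k1, l1 = r1.lw_modes(2, 10)
    k2, l2 = r2.lw_modes(2, 10)
    assert np.allclose(l1, l2, rtol=0.02)


def test_sw_exponent_picks_phi_pi(f1_spectrum_N100):
    r = f1_spectrum_N100
    lam_pi = sw_exponent(r)
    mask = ~r.is_field
    i = np.argmin(np.abs(r.wavenumbers[mask] - np.pi))
    assert lam_pi == r.lam[mask][i]


def test_field_sector_multipliers(f1, alpha3):
    """Weak coupling leaves the field multipliers near e^{-alpha T},
    assigned wavenumber phi = 0 by convention."""
    cfg = NetworkConfig(N=50, g=-0.1, field=f1, pulse=alpha3)
    fp = splay_fixed_point(cfg)
    r = floquet_spectrum_splay(cfg, fp)
    assert np.sum(r.is_field) == 2
    assert np.allclose(r.wavenumbers[r.is_field], 0.0)
    assert np.allclose(np.abs(r.multipliers[r.is_field]),
                       np.exp(-3.0 * fp.interspike_T), rtol=0.05)
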