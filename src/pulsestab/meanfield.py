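"""Thermodynamic-limit (N = infinity) spectral theory of the splay state.

In the infinite network the splay state is the stationary solution of
the continuity equation for the phase density; perturbations e^{lambda t}
obey the eigenvalue equation

    (e^{lambda/E} - 1) prod_k (lambda + alpha_k)
        = (g K lambda / E) int_0^1 dy e^{lambda y/E} / G(X(y)),

with E = 1/T0 the splay field amplitude, G(X) = g + T0 F(X), and
1/G(X(y)) the phase-response curve expressed in the phase variable y.
For weak coupling the roots move off the marginal values 2 pi i n / T0
proportionally to the PRC Fourier components (A_n, B_n), with closed
-form large-n asymptotics whose decay power is set jointly by the pulse
order L and the smoothness of F at the borders of the unit interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .fields import VelocityField, phase_map
from .pulses import PulseModel

__all__ = ["MeanField", "MeanFieldSpectrum", "meanfield_period",
           "asymptotic_real_part", "scaling_exponent_q", "lif_delta_limit"]


def meanfield_period(field: VelocityField, g: float) -> float:
    """Self-consistent splay period: int_0^1 dX / (g + T0 F(X)) = 1.

    This is the exact N -> infinity limit of the event-driven fixed
    point; it also normalizes the phase map (y(1) = 1) without any
    further rescaling.
    """
    grid = np.linspace(0.0, 1.0, 2001)
    fmin = float(np.min(field.evaluate(grid)))

    def resid(T):
        val, _ = quad(lambda x: 1.0 / (g + T * float(field.evaluate(x))), 0.0, 1.0,
                      epsabs=1e-12, epsrel=1e-12, limit=200)
        return val - 1.0

    lo = max(1e-8, -g / fmin * (1.0 + 1e-6)) if g < 0 else 1e-8
    # residual decreases with T: bracket by expansion
    hi = max(2.0 * field.free_period(), lo * 2.0)
    while resid(hi) > 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("no self-consistent period found")
    lo_try = lo + 1e-4 * (hi - lo)
    while resid(lo_try) < 0:
        lo_try = 0.5 * (lo + lo_try)
    return brentq(resid, lo_try, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)


@dataclass
class MeanFieldSpectrum:
    """One eigenvalue branch of the mean-field operator."""

    mode_index: int
    gamma_n: float
    eigenvalue: complex
    fourier_A: float
    fourier_B: float
    method: str


class MeanField:
    """Bundles the splay-state quantities needed by the spectral formulas.

    Parameters
    ----------
    field, pulse, g : the model; the pulse must have L >= 1 (delta-pulses
        have no decaying field sector and their modes do not shrink with n).
    T0 : optional period override; by default the self-consistent one.
    """

    def __init__(self, field: VelocityField, pulse: PulseModel, g: float,
                 T0: float | None = None):
        self.field = field
        self.pulse = pulse
        self.g = g
        self.T0 = meanfield_period(field, g) if T0 is None else float(T0)
        self.E_tilde = 1.0 / self.T0
        self.pm = phase_map(field, g, self.T0)
        self._Xy = self.pm.X_of_y_dense()

    # -- PRC Fourier components (Eqs. A_n + i B_n) --------------------
    def _prc(self, y):
        return 1.0 / self.pm.G(self._Xy(y))

    def fourier_prc(self, n: int,
                    method: Literal["quadrature", "asymptotic"] = "quadrature"):
        """Fourier components (A_n, B_n) of the PRC 1/G(X(y)).

        quadrature: composite Gauss-Legendre on oscillation-aligned
        panels (>= 20 per oscillation period).  asymptotic: the leading
        1/n expressions for a discontinuous F, involving only endpoint
        values of F, F' and G.
        """
        if n == 0:
            raise ValueError("mode index n must be nonzero")
        if method == "asymptotic":
            # two integrations by parts of int e^{2 pi i n y} / G(X(y)) dy:
            # the boundary jump of 1/G gives B_n ~ 1/n, the jump of its
            # y-derivative  d(1/G)/dy = -T0 F'(X)/G(X)  gives A_n ~ 1/n^2
            F, Fp, G = self.field.evaluate, self.field.derivative, self.pm.G
            F0, F1 = float(F(0.0)), float(F(1.0))
            G0, G1 = float(G(0.0)), float(G(1.0))
            A = -self.T0 / (4.0 * math.pi ** 2 * n ** 2) \
                * (float(Fp(1.0)) / G1 - float(Fp(0.0)) / G0)
            B = self.T0 / (2.0 * math.pi * n) * (F1 - F0) / (G1 * G0)
            return A, B
        m = abs(n)
        panels = max(40, 20 * m)
        nodes, weights = np.polynomial.legendre.leggauss(10)
        edges = np.linspace(0.0, 1.0, panels + 1)
        mid = 0.5 * (edges[:-1] + edges[1:])
        half = 0.5 * np.diff(edges)
        ys = (mid[:, None] + half[:, None] * nodes[None, :]).ravel()
        ws = (half[:, None] * weights[None, :]).ravel()
        vals = np.exp(2j * math.pi * n * ys) * self._prc(ys)
        z = np.sum(ws * vals)
        return float(z.real), float(z.imag)

    # -- Eq. 22: first order in g -------------------------------------
    def perturbative_eigenvalue(self, n: int) -> MeanFieldSpectrum:
        """lambda_n = 2 pi i n E [1 + gK(A_n + iB_n)/prod(2 pi i n E + alpha_k)]."""
        A, B = self.fourier_prc(n)
        gamma = 2.0 * math.pi * n * self.E_tilde
        denom = np.prod([1j * gamma + a for a in self.pulse.poles])
        lam = 1j * gamma * (1.0 + self.g * self.pulse.gain_K * (A + 1j * B) / denom)
        return MeanFieldSpectrum(n, gamma, complex(lam), A, B, "perturbative")

    # -- Eq. 19: exact root -------------------------------------------
    def _oscillatory_integral(self, lam: complex) -> complex:
        """int_0^1 dy e^{lam y / E} / G(X(y)) on oscillation-aligned panels."""
        m = max(1, int(abs(lam.imag) / (2.0 * math.pi * self.E_tilde) + 0.5))
        panels = max(40, 12 * m)
        nodes, weights = np.polynomial.legendre.leggauss(12)
        edges = np.linspace(0.0, 1.0, panels + 1)
        mid = 0.5 * (edges[:-1] + edges[1:])
        half = 0.5 * np.diff(edges)
        ys = (mid[:, None] + half[:, None] * nodes[None, :]).ravel()
        ws = (half[:, None] * weights[None, :]).ravel()
        return complex(np.sum(ws * np.exp(lam * ys / self.E_tilde) * self._prc(ys)))

    def _char(self, lam: complex) -> complex:
        E = self.E_tilde
        poly = np.prod([lam + a for a in self.pulse.poles])
        return (np.exp(lam / E) - 1.0) * poly \
            - self.g * self.pulse.gain_K * lam / E * self._oscillatory_integral(lam)

    def eigenvalue_equation_root(self, n: int, tol: float = 1e-12,
                                 maxiter: int = 100) -> MeanFieldSpectrum:
        """Newton iteration on the analytic eigenvalue equation, seeded at
        the marginal value 2 pi i n E (damped steps on divergence)."""
        if n == 0:
            raise ValueError("mode index n must be nonzero")
        lam = self.perturbative_eigenvalue(n).eigenvalue  # better-than-marginal seed
        f = self._char(lam)
        scale = 2.0 * math.pi * abs(n) * self.E_tilde
        for _ in range(maxiter):
            h = 1e-7 * (1.0 + abs(lam))
            df = (self._char(lam + h) - self._char(lam - h)) / (2.0 * h)
            step = f / df
            # damp steps that would jump to a neighbouring branch
            if abs(step) > 0.5 * scale:
                step *= 0.5 * scale / abs(step)
            lam_new = lam - step
            f_new = self._char(lam_new)
            tries = 0
            while abs(f_new) > abs(f) and tries < 8:
                step *= 0.5
                lam_new = lam - step
                f_new = self._char(lam_new)
                tries += 1
            if abs(lam_new - lam) < tol:
                lam = lam_new
                break
            lam, f = lam_new, f_new
        else:
            raise RuntimeError(f"Newton iteration did not converge for mode {n}")
        A, B = self.fourier_prc(n)
        return MeanFieldSpectrum(n, 2.0 * math.pi * n * self.E_tilde,
                                 complex(lam), A, B, "exact_root")

    def pole_sector_roots(self) -> np.ndarray:
        """Roots of prod(lambda + alpha_k) = g K sigma for constant PRC
        sigma (= the field poles -alpha_k when g = 0)."""
        sigma = 1.0  # constant-G normalization: int dy / G = 1
        coeffs = np.poly(np.array([-a for a in self.pulse.poles]))
        coeffs[-1] -= self.g * self.pulse.gain_K * sigma
        return np.roots(coeffs)


def scaling_exponent_q(L: int) -> int:
    """Decay power of Re lambda_n ~ n^{-q} for a discontinuous field:
    q = 2 floor((L+1)/2)."""
    return 2 * ((L + 1) // 2)


def asymptotic_real_part(field: VelocityField, pulse: PulseModel, g: float,
                         T0: float, n: int, mf: MeanField | None = None) -> float:
    """Leading large-n real part of the mean-field eigenvalues.

    Even L, discontinuous F:
        Re lambda_n = g K T0^L (-1)^{L/2} (F(0)-F(1)) / ((2 pi n)^L G(1) G(0));
    odd L:
        the endpoint values of F and F' mix (see the bracketed term);
    continuous F with even L: Re lambda_n ~ n^{-(L+2)}, with the
    coefficient measured numerically from the first-order eigenvalue
    (the closed-form constant involves higher endpoint derivatives).
    """
    L = pulse.order_L
    if L == 0:
        raise ValueError("delta-pulses: eigenvalue magnitudes do not decay with n")
    K, S = pulse.gain_K, pulse.pole_sum_S
    F, Fp = field.evaluate, field.derivative
    F0, F1 = float(F(0.0)), float(F(1.0))
    G = lambda x: g + T0 * float(F(x))
    G0, G1 = G(0.0), G(1.0)
    discontinuous = abs(F0 - F1) > 1e-9

    if L % 2 == 0:
        if discontinuous:
            return g * K * T0 ** L * (-1.0) ** (L // 2) * (F0 - F1) \
                / ((2.0 * math.pi * n) ** L * G1 * G0)
        mf = mf or MeanField(field, pulse, g, T0=T0)
        n_ref = 48
        c = mf.perturbative_eigenvalue(n_ref).eigenvalue.real * n_ref ** (L + 2)
        return c / n ** (L + 2)
    # odd L: expanding prod(alpha_k - i gamma_n) to its two leading terms
    # gives Re lambda ~ gK(-1)^{(L+1)/2} [-A_n + S B_n/gamma]/gamma^{L-1}
    bracket = float(Fp(1.0)) / G1 - float(Fp(0.0)) / G0 \
        + S * T0 * (F1 - F0) / (G1 * G0)
    return g * K * T0 ** L * (-1.0) ** ((L + 1) // 2) \
        / (2.0 * math.pi * n) ** (L + 1) * bracket


def lif_delta_limit(a: float, T0: float) -> float:
    """delta-pulse limit of the LIF short-wavelength exponent:
    lim lambda_pi = -1 + ln(a/(a-1)) / T0  (T0 the coupled network period)."""
    if a <= 1.0:
        raise ValueError("LIF offset must satisfy a > 1 (supra-threshold)")
    if T0 <= 0:
        raise ValueError("period must be positive")
    return -1.0 + math.log(a / (a - 1.0)) / T0
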