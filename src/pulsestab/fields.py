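"""Single-neuron velocity fields F(X) and the phase change of variables.

The membrane potential X of every neuron lives on [0, 1] and obeys
Xdot = F(X) + g E(t); F must be strictly positive on [0, 1] so that the
neuron is repetitively firing (supra-threshold).  The smoothness of F at
the borders of the unit interval — viewed as a periodic continuation,
since the reset identifies X=1 with X=0 — controls the decay of the
long-wavelength Floquet exponents of the splay state, which is why each
field carries an explicit continuity class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq

__all__ = ["VelocityField", "field_catalog", "constant_field", "PhaseMap", "phase_map"]

_CLASSES = ("discontinuous", "C0", "Cinf")

#: grid used for the construction-time positivity check
_POSITIVITY_GRID = np.linspace(0.0, 1.0, 10_001)


@dataclass(frozen=True)
class VelocityField:
    """A velocity law F(X) on the unit interval with its derivative.

    Parameters
    ----------
    name : short identifier (e.g. ``"F0"``).
    evaluate, derivative : vectorized callables for F and F'.
    continuity_class : ``"discontinuous"`` (F(0) != F(1)), ``"C0"``
        (F continuous at the borders but F' is not) or ``"Cinf"``
        (smooth periodic continuation).
    param_a : the offset parameter a entering every catalog field.
    """

    name: str
    evaluate: Callable[[np.ndarray], np.ndarray]
    derivative: Callable[[np.ndarray], np.ndarray]
    continuity_class: str
    param_a: float

    def __post_init__(self) -> None:
        if self.continuity_class not in _CLASSES:
            raise ValueError(f"unknown continuity class {self.continuity_class!r}")
        vals = np.asarray(self.evaluate(_POSITIVITY_GRID), dtype=float)
        if not np.all(vals > 0.0):
            i = int(np.argmin(vals))
            raise ValueError(
                f"velocity field {self.name!r} is not positive on [0,1]: "
                f"F({_POSITIVITY_GRID[i]:.4f}) = {vals[i]:.4g} (a={self.param_a})"
            )
        measured = self._measured_class()
        if measured != self.continuity_class:
            raise ValueError(
                f"continuity class {self.continuity_class!r} of {self.name!r} "
                f"disagrees with endpoint values (measured {measured!r})"
            )

    def _measured_class(self, tol: float = 1e-9) -> str:
        f0, f1 = float(self.evaluate(0.0)), float(self.evaluate(1.0))
        if abs(f0 - f1) > tol:
            return "discontinuous"
        d0, d1 = float(self.derivative(0.0)), float(self.derivative(1.0))
        if abs(d0 - d1) > tol:
            return "C0"
        return "Cinf"

    def __call__(self, x):
        return self.evaluate(x)

    def free_period(self) -> float:
        """Uncoupled interspike period T0 = int_0^1 dX / F(X)."""
        val, _ = quad(lambda x: 1.0 / float(self.evaluate(x)), 0.0, 1.0,
                      epsabs=1e-13, epsrel=1e-13, limit=200)
        return val


def _catalog_entry(name: str, a: float):
    pi = math.pi
    if name == "F0":
        return (lambda x: a - np.asarray(x, float),
                lambda x: -np.ones_like(np.asarray(x, float)),
                "discontinuous")
    if name == "F1":
        return (lambda x: a - np.asarray(x, float) * (np.asarray(x, float) - 0.7),
                lambda x: 0.7 - 2.0 * np.asarray(x, float),
                "discontinuous")
    if name == "F2":
        return (lambda x: a - 0.25 * np.sin(pi * np.asarray(x, float)),
                lambda x: -0.25 * pi * np.cos(pi * np.asarray(x, float)),
                "C0")
    if name == "F3":
        return (lambda x: a + np.asarray(x, float) * (np.asarray(x, float) - 1.0),
                lambda x: 2.0 * np.asarray(x, float) - 1.0,
                "C0")
    if name == "F4":
        return (lambda x: a - 0.25 * np.sin(pi * np.asarray(x, float))
                * np.cos(pi * np.asarray(x, float)) ** 2,
                lambda x: -0.25 * pi * (np.cos(pi * np.asarray(x, float)) ** 3
                                        - 2.0 * np.sin(pi * np.asarray(x, float)) ** 2
                                        * np.cos(pi * np.asarray(x, float))),
                "C0")
    if name == "F5":
        return (lambda x: a - 0.25 * np.sin(2 * pi * np.asarray(x, float))
                * np.cos(2 * pi * np.asarray(x, float)) ** 2,
                lambda x: -0.5 * pi * (np.cos(2 * pi * np.asarray(x, float)) ** 3
                                       - 2.0 * np.sin(2 * pi * np.asarray(x, float)) ** 2
                                       * np.cos(2 * pi * np.asarray(x, float))),
                "Cinf")
    if name == "F6":
        def f6(x):
            x = np.asarray(x, float)
            return a - 0.25 * np.sin(2 * pi * x) * np.exp(np.cos(2 * pi * x))

        def df6(x):
            x = np.asarray(x, float)
            e = np.exp(np.cos(2 * pi * x))
            return -0.25 * 2 * pi * e * (np.cos(2 * pi * x) - np.sin(2 * pi * x) ** 2)
        return (f6, df6, "Cinf")
    if name == "F7":
        def f7(x):
            x = np.asarray(x, float)
            return a - 1.0 + np.exp(2.0 * np.sin(2 * pi * x))

        def df7(x):
            x = np.asarray(x, float)
            return 4.0 * pi * np.cos(2 * pi * x) * np.exp(2.0 * np.sin(2 * pi * x))
        return (f7, df7, "Cinf")
    raise KeyError(f"unknown velocity field {name!r}; catalog is F0..F7")


def field_catalog(name: str, a: float = 1.3) -> VelocityField:
    """Return a catalog velocity field.

    ``F0 = a - X`` is the leaky integrate-and-fire neuron; F1 is a
    discontinuous quadratic, F2-F4 are continuous with a derivative
    mismatch at the borders, F5-F7 have a smooth periodic continuation.
    Positivity on [0,1] is checked at construction and violations are
    rejected with a diagnostic.
    """
    evaluate, derivative, cls = _catalog_entry(name, a)
    return VelocityField(name=name, evaluate=evaluate, derivative=derivative,
                         continuity_class=cls, param_a=a)


def constant_field(c: float) -> VelocityField:
    """A constant velocity field F(X) = c (a pure phase rotator)."""
    if c <= 0:
        raise ValueError("constant field must be positive")
    return VelocityField(
        name=f"const({c})",
        evaluate=lambda x: c * np.ones_like(np.asarray(x, float)),
        derivative=lambda x: np.zeros_like(np.asarray(x, float)),
        continuity_class="Cinf",
        param_a=c,
    )


@dataclass
class PhaseMap:
    """The phase-like variable y(X) = int_0^X dx / G(x), G = g + T0 F.

    1/G is a probability-density-like weight: y(0) = 0, y(1) = 1.  For
    the self-consistent splay period T0 the normalization integral
    int_0^1 dx/G equals one exactly; for any other T0 the map is
    normalized explicitly.  The inverse X(y) is obtained by a bracketed
    root-find to 1e-12.
    """

    field: VelocityField
    g: float
    period_T0: float
    _norm: float = dc_field(init=False, repr=False, default=1.0)

    def __post_init__(self) -> None:
        gmin = float(np.min(self.G(_POSITIVITY_GRID)))
        if gmin <= 0.0:
            xbad = _POSITIVITY_GRID[int(np.argmin(self.G(_POSITIVITY_GRID)))]
            raise ValueError(
                f"G(X) = g + T0 F(X) crosses zero near X = {xbad:.4f} "
                f"(g = {self.g}, T0 = {self.period_T0}); coupling too negative"
            )
        self._norm = self._raw_y(1.0)

    @property
    def E_tilde(self) -> float:
        """Splay-state field amplitude, 1/T0."""
        return 1.0 / self.period_T0

    def G(self, x):
        return self.g + self.period_T0 * np.asarray(self.field.evaluate(x), float)

    def _raw_y(self, x: float) -> float:
        val, _ = quad(lambda s: 1.0 / float(self.G(s)), 0.0, x,
                      epsabs=1e-12, epsrel=1e-12, limit=200)
        return val

    def y_of_X(self, x):
        if np.ndim(x) == 0:
            return self._raw_y(float(x)) / self._norm
        return np.array([self._raw_y(float(xi)) for xi in np.ravel(x)]).reshape(np.shape(x)) / self._norm

    def X_of_y(self, y):
        def inv(yv: float) -> float:
            if yv <= 0.0:
                return 0.0
            if yv >= 1.0:
                return 1.0
            return brentq(lambda x: self._raw_y(x) / self._norm - yv, 0.0, 1.0,
                          xtol=1e-12, rtol=8.9e-16)
        if np.ndim(y) == 0:
            return inv(float(y))
        return np.array([inv(float(yi)) for yi in np.ravel(y)]).reshape(np.shape(y))

    def X_of_y_dense(self, n_grid: int = 4097):
        """High-accuracy dense inverse: integrate dX/dy = norm * G(X).

        Returns a callable backed by the dense output of a DOP853 solve;
        used by the mean-field quadratures, where many evaluations of
        X(y) are needed.
        """
        norm = self._norm
        sol = solve_ivp(lambda y, x: norm * self.G(x[0]).reshape(1), (0.0, 1.0), [0.0],
                        method="DOP853", rtol=1e-13, atol=1e-14, dense_output=True)
        if not sol.success:
            raise RuntimeError("phase-map inversion integration failed")

        def X(y):
            y = np.clip(np.asarray(y, float), 0.0, 1.0)
            return np.clip(sol.sol(np.ravel(y))[0].reshape(np.shape(y)), 0.0, 1.0)
        return X


def phase_map(field: VelocityField, g: float, T0: float) -> PhaseMap:
    """Build the phase change of variables y(X) for coupling g, period T0."""
    return PhaseMap(field=field, g=g, period_T0=T0)
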