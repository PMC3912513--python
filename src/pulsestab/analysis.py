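"""Scaling-law extraction and figure-style reproduction pipelines.

The quantitative content of the stability analysis is a set of power
laws: how the short-wavelength Floquet exponent shrinks with network
size N (1/N^2 for discontinuous velocity fields with alpha-pulses,
1/N^4 for C0 fields, 1/N for C0 fields with N-scaled pulses, finite for
discontinuous fields with N-scaled pulses), how the long-wavelength
branch decays with mode index k, and how the same laws carry over to
the Lyapunov spectra of the periodically forced network.  This module
turns those statements into machine-checkable log-log fits and bundles
the pipelines that regenerate each figure-style study at desk scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .config import NetworkConfig, dump_config
from .fields import field_catalog
from .meanfield import MeanField, asymptotic_real_part
from .pulses import PulseModel
from .splay_floquet import FloquetResult, floquet_spectrum_splay, sw_exponent

__all__ = ["ScalingFit", "fit_power_law", "splay_spectrum_study",
           "sw_scaling_study", "forced_scaling_study", "reproduce_figure",
           "FIGURE_TAGS"]


@dataclass
class ScalingFit:
    """Least-squares power law y ~ x^slope on log-log axes."""

    abscissa: np.ndarray
    values: np.ndarray
    slope: float
    stderr: float
    intercept: float
    fit_range: tuple

    @property
    def exponent_magnitude(self) -> float:
        return abs(self.slope)


def fit_power_law(xs, ys, fit_range: tuple | None = None) -> ScalingFit:
    """Fit log|y| vs log x by least squares over an optional x-range.

    All values inside the range must be positive magnitudes; at least
    three points are required for a meaningful slope and error bar.
    """
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    if fit_range is not None:
        m = (xs >= fit_range[0]) & (xs <= fit_range[1])
        xs, ys = xs[m], ys[m]
    if len(xs) < 3:
        raise ValueError("power-law fit needs at least three points")
    if np.any(ys <= 0.0):
        raise ValueError("power-law fit needs positive magnitudes in range")
    res = stats.linregress(np.log(xs), np.log(ys))
    return ScalingFit(abscissa=xs, values=ys, slope=float(res.slope),
                      stderr=float(res.stderr), intercept=float(res.intercept),
                      fit_range=(float(xs.min()), float(xs.max())))


def splay_spectrum_study(config: NetworkConfig) -> FloquetResult:
    """Single splay Floquet spectrum (convenience wrapper)."""
    return floquet_spectrum_splay(config)


def sw_scaling_study(field_name: str, pulse: PulseModel, g: float,
                     Ns: Sequence[int], a: float = 1.3):
    """|lambda(phi = pi)| at each N plus its log-log slope in N."""
    field = field_catalog(field_name, a)
    vals = []
    for N in Ns:
        cfg = NetworkConfig(N=N, g=g, field=field, pulse=pulse)
        vals.append(abs(sw_exponent(floquet_spectrum_splay(cfg))))
    fit = fit_power_law(np.asarray(Ns, float), np.asarray(vals))
    return np.asarray(vals), fit


def forced_spectrum_magnitude(exponents: np.ndarray, N: int,
                              estimator: str = "median") -> float:
    """Scalar magnitude of a forced Lyapunov spectrum for N-scaling fits.

    The two field exponents (the most negative pair, near -alpha) and the
    two neutral directions (flow and forcing phase, the smallest
    magnitudes) are removed first.  ``median`` takes the median of the
    remaining potential-sector magnitudes — the spectral bulk, which
    collapses as the predicted power of 1/N.  ``fixed_phi`` instead
    log-interpolates |lambda| at wavenumber phi = pi/3 (mode k = N/6,
    sorted magnitudes paired by k); it probes the best-converged large
    modes and is the usable observable when the spectral tail is smaller
    than the finite-time resolution (see the methods note).
    """
    lam = np.sort(np.asarray(exponents))[2:]          # drop the field pair
    mags = np.sort(np.abs(lam))[2:][::-1]             # drop neutrals; descending
    if estimator == "median":
        return float(np.median(mags))
    if estimator == "fixed_phi":
        # conjugate pairs share a wavenumber: geometric-mean the partners
        # so slot k holds |lambda_k|, then interpolate log-log in k
        m = len(mags) // 2
        pair = np.sqrt(mags[0:2 * m:2] * mags[1:2 * m:2])
        ks = np.arange(1, m + 1, dtype=float)
        k_target = min(max(N / 6.0, 1.0), float(m))
        return float(np.exp(np.interp(np.log(k_target), np.log(ks),
                                      np.log(pair))))
    raise ValueError(f"unknown estimator {estimator!r}")


def forced_scaling_study(field_name: str, g: float, Ns: Sequence[int],
                         alpha: float = 3.0, A: float = 0.1, Ta: float = 2.0,
                         seed: int = 1, a: float = 1.3,
                         n_spikes_per_N: dict | None = None,
                         estimator: str = "median"):
    """Forced Lyapunov-spectrum magnitude at each N and its N-slope.

    n_spikes_per_N maps N -> measurement spikes; the finite-time error
    of the exponents decays slowly (roughly as 1/sqrt(t)), so the
    measurement window must grow quickly with N for the shrinking
    spectra to stay resolved (problem sizes in the methods note).
    """
    from .forced import lyapunov_spectrum  # deferred: numba compilation
    field = field_catalog(field_name, a)
    meds = []
    for N in Ns:
        cfg = NetworkConfig(N=N, g=g, field=field,
                            pulse=PulseModel.alpha_pulse(alpha),
                            forcing_A=A, forcing_Ta=Ta)
        n_meas = None if n_spikes_per_N is None else n_spikes_per_N[N]
        r = lyapunov_spectrum(cfg, n_spikes=n_meas, seed=seed)
        meds.append(forced_spectrum_magnitude(r.exponents, N, estimator))
    fit = fit_power_law(np.asarray(Ns, float), np.asarray(meds))
    return np.asarray(meds), fit


# ----------------------------------------------------------------------
# figure-style reproduction pipelines
# ----------------------------------------------------------------------

FIGURE_TAGS = ("fig1a", "fig1b", "fig2", "fig3a", "fig3b", "fig4",
               "fig5", "fig6")

#: expected integer exponents of the headline power laws
_EXPECTED = {"fig1a": ("k", 2), "fig1b": ("k", 4), "fig2": ("k", 4),
             "fig3b": ("N", 1), "fig5": ("N", 2), "fig6": ("N", 4)}


def _exponential_rate(r: FloquetResult) -> dict:
    """Log-linear decay rate of |lambda_k| over its monotone exponential
    prefix (analytic fields cross over to a weak second-order background
    after several modes, which must not enter the fit)."""
    k, lam = r.lw_modes(1, 60)
    mag = np.abs(lam)
    end = 1
    while end < len(mag) and mag[end] < mag[end - 1] and mag[end] > 1e-11:
        end += 1
    end = max(end, 4)
    fit = stats.linregress(k[:end].astype(float), np.log(mag[:end]))
    return {"rate": float(fit.slope), "r2": float(fit.rvalue ** 2),
            "k_max": int(k[end - 1])}


def _spectrum_frame(r: FloquetResult):
    import pandas as pd
    return pd.DataFrame({
        "k": r.k_index, "phi_k": r.wavenumbers, "lambda_k": r.lam,
        "omega_k": r.omega, "abs_mu_k": np.abs(r.multipliers),
        "is_field": r.is_field.astype(int),
    })


def reproduce_figure(tag: str, outdir, scale: str = "reduced",
                     seed: int = 1, make_plot: bool = True) -> dict:
    """Re-run one figure-style study at desk scale.

    Writes per-curve CSVs, a JSON report with the fitted exponents and
    pass/fail verdicts against the expected integer power (tolerance
    0.3), and optionally a PNG overview plot.  All pipelines are
    deterministic given (tag, scale, seed).
    """
    if tag not in FIGURE_TAGS:
        raise ValueError(f"unknown figure tag {tag!r}; choose from {FIGURE_TAGS}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    a, alpha, beta = 1.3, 3.0, 0.03
    g = -0.4
    Ns = (50, 100, 200) if scale == "reduced" else (100, 200, 400)
    report: dict = {"tag": tag, "scale": scale, "seed": seed, "curves": {},
                    "fits": {}, "verdicts": {}}
    curves = {}

    def splay_run(fname, pulse, N, gg=g):
        cfg = NetworkConfig(N=N, g=gg, field=field_catalog(fname, a), pulse=pulse)
        return floquet_spectrum_splay(cfg)

    if tag in ("fig1a", "fig3a"):
        pulse = PulseModel.alpha_pulse(alpha) if tag == "fig1a" else PulseModel.beta_pulse(beta)
        mf = MeanField(field_catalog("F1", a), PulseModel.alpha_pulse(alpha), g)
        for N in Ns:
            r = splay_run("F1", pulse, N)
            curves[f"F1_N{N}"] = r
        ks = np.arange(1, Ns[-1] // 2 + 1)
        pl = pulse.resolve(Ns[-1])
        theory = np.array([asymptotic_real_part(mf.field, pl, g, mf.T0, int(k))
                           for k in ks])
        report["curves"]["eq30_theory"] = {"k": ks.tolist(),
                                           "re_lambda": theory.tolist()}
        r_big = curves[f"F1_N{Ns[-1]}"]
        if tag == "fig1a":
            k, lam = r_big.lw_modes(5, Ns[-1] // 10)
            fit = fit_power_law(k, np.abs(lam))
            report["fits"]["lw_k_slope"] = {"slope": fit.slope, "stderr": fit.stderr}
            report["verdicts"]["lw_k_slope_2"] = bool(abs(abs(fit.slope) - 2) < 0.3)
        else:
            sw = {N: abs(sw_exponent(curves[f"F1_N{N}"])) for N in Ns}
            spread = max(sw.values()) / min(sw.values()) - 1.0
            report["fits"]["sw_values"] = {str(N): v for N, v in sw.items()}
            report["verdicts"]["sw_N_independent_10pct"] = bool(spread < 0.10)

    elif tag in ("fig1b", "fig2"):
        fields = ["F4"] if tag == "fig1b" else ["F2", "F4", "F6", "F7"]
        pulse = PulseModel.alpha_pulse(alpha)
        for fname in fields:
            r = splay_run(fname, pulse, Ns[-1])
            curves[f"{fname}_N{Ns[-1]}"] = r
            if fname in ("F2", "F4"):
                k, lam = r.lw_modes(5, Ns[-1] // 10)
                fit = fit_power_law(k, np.abs(lam))
                report["fits"][f"{fname}_k_slope"] = {"slope": fit.slope,
                                                      "stderr": fit.stderr}
                report["verdicts"][f"{fname}_k_slope_4"] = bool(abs(abs(fit.slope) - 4) < 0.3)
            else:
                # analytic fields: exponential decay, fit log|lambda| vs k
                rate = _exponential_rate(r)
                report["fits"][f"{fname}_exp_rate"] = rate
                report["verdicts"][f"{fname}_exponential"] = bool(rate["r2"] > 0.9)
        if tag == "fig1b":
            mf = MeanField(field_catalog("F4", a), pulse, g)
            ks = np.arange(1, Ns[-1] // 2 + 1)
            th = [mf.perturbative_eigenvalue(int(k)).eigenvalue.real for k in ks]
            report["curves"]["eq22_theory"] = {"k": ks.tolist(), "re_lambda": th}

    elif tag == "fig3b":
        pulse = PulseModel.beta_pulse(beta)
        sw = []
        for N in Ns:
            r = splay_run("F2", pulse, N)
            curves[f"F2_N{N}"] = r
            sw.append(abs(sw_exponent(r)))
        fit = fit_power_law(np.asarray(Ns, float), np.asarray(sw))
        report["fits"]["sw_N_slope"] = {"slope": fit.slope, "stderr": fit.stderr}
        report["verdicts"]["sw_N_slope_1"] = bool(abs(abs(fit.slope) - 1) < 0.3)

    elif tag == "fig4":
        pulse = PulseModel.beta_pulse(beta)
        for N in Ns[:2]:
            r = splay_run("F7", pulse, N)
            curves[f"F7_N{N}"] = r
        rate = _exponential_rate(curves[f"F7_N{Ns[1]}"])
        report["fits"]["exp_rate"] = rate
        report["verdicts"]["exponential_decay"] = bool(rate["r2"] > 0.9)

    elif tag in ("fig5", "fig6"):
        # forced Lyapunov N-scaling; stable-splay excitatory coupling
        fnames = ("F0", "F1") if tag == "fig5" else ("F3",)
        expect = _EXPECTED[tag][1]
        if tag == "fig5":
            Ns_f = (12, 18, 27)
            estimator = "median"
            factors = {12: 8000, 18: 16000, 27: 32000}
        else:
            # the 1/N^4 tail falls below the finite-time resolution for
            # N >= 18 at desk scale: probe |lambda| at fixed phi instead
            Ns_f = (8, 10, 12)
            estimator = "fixed_phi"
            factors = {8: 16000, 10: 24000, 12: 32000}
        if scale == "full":
            factors = {N: 2 * f for N, f in factors.items()}
        spikes = {N: factors[N] * N for N in Ns_f}
        for fname in fnames:
            meds, fit = forced_scaling_study(fname, 0.3, Ns_f, seed=seed,
                                             n_spikes_per_N=spikes,
                                             estimator=estimator)
            report["fits"][f"{fname}_N_slope"] = {"slope": fit.slope,
                                                  "stderr": fit.stderr,
                                                  "magnitudes": meds.tolist(),
                                                  "Ns": list(Ns_f),
                                                  "estimator": estimator}
            tol = 0.4 if tag == "fig5" else 0.5
            report["verdicts"][f"{fname}_N_slope_{expect}"] = \
                bool(abs(abs(fit.slope) - expect) < tol)

    # ---- outputs ----
    for name, r in curves.items():
        _spectrum_frame(r).to_csv(outdir / f"{tag}_{name}.csv", index=False,
                                  float_format="%.12e")
        report["curves"][name] = {"file": f"{tag}_{name}.csv",
                                  "config": dump_config(r.config)}
    if make_plot and curves:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 4.2))
        for name, r in curves.items():
            k, lam = r.lw_modes(1)
            ax.loglog(k, np.abs(lam), ".", ms=3, label=name)
        ax.set_xlabel("mode index k")
        ax.set_ylabel(r"$|\lambda_k|$")
        ax.legend(fontsize=7)
        ax.set_title(tag)
        fig.tight_layout()
        fig.savefig(outdir / f"{tag}.png", dpi=120)
        plt.close(fig)
    with open(outdir / f"{tag}_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
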