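# Methods

## Model

A network of N identical pulse-coupled rotators. Each membrane
potential obeys

    dX^j/dt = F(X^j) + g E(t),        j = 1..N,

on the unit interval: when X^j reaches the threshold 1 it is reset to 0
and a spike is added to the common synaptic field E(t). F(X) > 0
everywhere (supra-threshold: every neuron fires repetitively);
F0(X) = a − X is the leaky integrate-and-fire neuron, and the catalog
F0..F7 spans the three smoothness classes of the periodic continuation
of F at the reset border — discontinuous (F(0) ≠ F(1)), continuous with
a derivative break (C0), and smooth (C∞). g is the coupling constant,
negative for inhibition.

The field is the superposition of unit-area pulses generated by a
linear filter of order L with poles −α_k and gain K = Π α_k: each spike
adds K/N to E^(L−1). L = 0 are instantaneous δ-pulses (no field
dynamics, each spike kicks every other potential by g/N), L = 1
discontinuous exponentials, L = 2 with a double pole the α-pulse
α² t e^{−αt}. β-pulses are α-pulses with α = βN, keeping the pulse
width comparable to the network interspike interval T0/N. Internally
the field state is the companion vector (E, E′, …, E^(L−1)); its
propagator is exact (closed forms for L ≤ 2, eigendecomposition for
distinct poles, `scipy.linalg.expm` for repeated poles of order > 2 — a
slow but exact fallback).

## Event-driven map

Because the field ODE is linear, E(t) between spikes is known in closed
form, and the network can be advanced spike-to-spike exactly: the
interspike interval T solves the threshold condition Φ(X^1, field, T)=1
for the largest potential, all potentials are propagated by the flow,
labels are shifted backward (neurons never overtake each other — they
share one velocity field), the firer is reset, and the field receives
its jump at the end of the interval. Threshold times are found by
bracketed root solving on dense solver output (|X − 1| ≲ 1e−13); small
negative intervals are admitted so that near-degenerate (synchronous)
states can be probed by infinitesimal perturbations.

**Splay fixed point.** For trial T the periodic field state is
ṽ = (I − e^{CT})^{-1}(K/N)e_L in closed form, so the whole fixed point
reduces to a scalar root solve on T: the residual is the single
trajectory 0 → 1 under the T-periodic field, integrated over [0, NT].
The coarse root is found by bracket expansion plus Brent on that
residual, then polished by a secant iteration on the kink-free
per-interval backward chain (X̃^j = Φ(X̃^{j+1}, T) from X̃^N = 0) to a
residual below 1e−12. δ-pulse networks use time-of-flight coordinates
Θ(X) = ∫dX/F and its inverse, both dense-output integrations accurate
to ~1e−12.

## Splay Floquet spectra

The one-interspike tangent map is assembled from variational
integration, never finite differences: per trajectory the coefficients
(Φ_X, Φ_v) solve D′ = F′(X(t))D and b′_m = F′(X(t))b_m + g(e^{Ct})_{0m}
alongside the flow (DOP853, rtol 1e−12, atol 1e−14; all N trajectories
in one vectorized solve). The spike contributes the crossing-time
linearization τ = −(Φ_X x^1 + Φ_v·δv)/V¹ with V¹ the threshold
velocity; every row gains its end-velocity times τ, and the field rows
gain v̇(T⁻)τ. The matrix is validated against a centered
finite-difference Jacobian of the nonlinear map (N = 6, deviation
< 1e−5), for α-, exponential and δ-pulses.

Multipliers are unfolded as μ_k = e^{iϕ_k} e^{T0(λ_k + iω_k)/N} with
wavenumbers ϕ_k = 2πk/N: the L field multipliers (closest to the
eigenvalues of the bare field propagator, ϕ = 0 by convention) are
peeled off first, the rest are matched to the ordered wavenumbers by
their complex argument. λ at ϕ = π is the canonical short-wavelength
(SW) magnitude; the long-wavelength (LW) branch is λ_k at small k.
Exponents below ~1e−11 (analytic fields) are numerical noise and are
not interpreted.

## Synchronous state

With all neurons on one trajectory the period must be decomposed into N
event-driven steps: one finite step 0 → 1 in which the first neuron
crosses, then N−1 zero-length crossings handled **symbolically** (exact
matrices; nothing is integrated over a vanishing interval). Each
zero-length crossing contributes −V^j/V¹ in the first column (V⁰, V¹
the velocities at reset and threshold) and ones on the supradiagonal,
while the auxiliary field variable advances in K/N increments as the
neurons cross one after the other. The product of the N matrices is
verified to have an exactly diagonal potential block (off-diagonal
contamination < 1e−8 raises an error): the synchronous spectrum is
degenerate, Λ_jj identical for all j and independent of N, plus an L×L
field block. The product equals the finite-difference Jacobian of N
nonlinear event steps (N = 4, < 1e−5).

The evaporation exponent Λ_e — the stability of a probe neuron riding
the frozen periodic mean field with no feedback — is computed one-sided
from the drift of the probe's firing-time offset over one period,
integrating segment-by-segment so the field jumps at the cluster's
firing times never fall inside a solver step. The probe displacement
is δ = 2e−6 with Richardson extrapolation in δ (the crossing-time map
has one-sided curvature); at δ ~ 1e−7 the integration noise floor
(~1e−13 in crossing times) would dominate the exponent, which is why
the displacement is larger than one might naively pick. For α-pulses
both sides equal ln(Λ_jj)/T to ~1e−7. For exponential pulses the field
jump at the cluster spike breaks the symmetry: in the weak-coupling
regime (|g|α < F(1), so velocities stay positive after the jump) the
late-probe side reproduces ln(Λ_jj)/T and the early side has opposite
sign; at stronger inhibition a late probe is pushed back across
threshold by the jump and escapes by a finite time offset — the
reported positive rate is then δ-dependent but its sign is the robust
statement.

## Mean-field (N = ∞) theory

The splay period solves the self-consistency ∫₀¹ dX/(g + T0 F(X)) = 1
— the exact thermodynamic limit, which also normalizes the phase map
y(X) = ∫₀^X dx/G(x), G = g + T0·F, without rescaling (we prefer this
over extrapolating a large-N fixed point: it is what the eigenvalue
equation presumes and carries no O(1/N) bias). Perturbation
eigenvalues solve

    (e^{λ/Ẽ} − 1) Π(λ + α_k) = (gKλ/Ẽ) ∫₀¹ dy e^{λy/Ẽ} / G(X(y)),

Ẽ = 1/T0. Exact roots: damped Newton seeded at the first-order value,
with the oscillatory integral on composite Gauss–Legendre panels
aligned with the oscillation (≥ 12 per period); X(y) from the dense
output of a single dX/dy = G integration. First order in g:
λ_n = 2πinẼ[1 + gK(A_n + iB_n)/Π(2πinẼ + α_k)] with (A_n, B_n) the
Fourier components of the phase-response curve 1/G(X(y)) (quadrature
panels ≥ 20 per oscillation).

Large-n closed forms follow from two integrations by parts: the
boundary jump of 1/G gives B_n ≃ T0(F(1)−F(0))/(2πn G(1)G(0)); the
jump of its y-derivative, d(1/G)/dy = −T0F′(X)/G(X), gives
A_n ≃ −T0[F′(1)/G(1) − F′(0)/G(0)]/(4π²n²). Note the single power of
G in the A_n bracket — the derivation fixes it, and quadrature confirms
it (the bracket with squared G's misses by a constant factor). For
even L and discontinuous F the leading real part is

    Re λ_n = gK T0^L (−1)^{L/2} (F(0) − F(1)) / ((2πn)^L G(1)G(0)),

for odd L it is gK T0^L (−1)^{(L+1)/2}/(2πn)^{L+1} times
[F′(1)/G(1) − F′(0)/G(0) + S T0 (F(1)−F(0))/(G(1)G(0))], S = Σα_k
(sign of the S-term again fixed by the expansion and verified against
quadrature). The decay power for discontinuous F is q = 2⌊(L+1)/2⌋;
for continuous F with even L the exponents fall as n^{−(L+2)}, with the
coefficient measured from the first-order eigenvalue at a reference
mode (n = 48) since it involves higher endpoint derivatives. For L = 0
(δ-pulses) the eigenvalues do not decay with n at all. The LIF
δ-pulse SW limit is λ_π → −1 + ln(a/(a−1))/T0 with T0 the coupled
network period.

## Periodic forcing and Lyapunov spectra

With a common drive A cos(2πt/T_a) the system is autonomous in
(X, E, P, φ) and is integrated by fixed-step RK4. Spike times are
located by the variable-exchange step: when X^1 overshoots, the step is
retracted and one RK4 step is taken with X^1 as independent variable
(step 1 − X^1), landing on the threshold exactly. The Lyapunov
spectrum propagates a full orthonormal tangent frame with the
linearized equations, QR-reorthonormalized at every spike. The event
correction of a tangent vector w compares trajectories at fixed time:
with τ = −w_{x¹}/V¹, w⁺ = Dg·w − (f⁺ − Dg·f⁻)τ — the reset slot gets
−V⁰τ and the field rows −(α²/N)τ and +(α³/N)τ. (This differs by a
sign from the Poincaré-section convention of the event-driven Floquet
matrix, where the comparison time moves with the perturbed event.)
Validated by the A = 0 limit, which reproduces the splay Floquet
spectrum mode-for-mode (field pair to ~1e−4 relative), and by a
finite-difference trajectory pair.

Defaults: dt = min(T̃, T_a)/20 with T̃ the unforced interspike interval
(step-halving changes the exponents by < 1% of the spectral scale;
RK4 at this step is far more accurate than the exponent resolution),
transient 200N spikes, initial condition = unforced splay plus 1e−6
seeded jitter. The forced studies use weak excitatory coupling
g = +0.3: the forced regime is defined around a **stable** splay state,
and for F0/F1/F3 with α-pulses stability requires g > 0 (the sign of
the leading closed form above). The splay-side scaling studies use
g = −0.4; all fitted scaling exponents are insensitive to the choice of
weak |g|, only overall prefactors and stability signs move.

### Problem sizes for the forced scaling fits

Finite-time Lyapunov estimates of this quasi-periodic system converge
slowly: the potential-sector band is nearly degenerate (spacings down
to 1e−5 and below), and separating directions whose rates differ by Δλ
intrinsically requires times of order 1/Δλ; empirically the error of a
band exponent decays like ~0.01/√t. The fits therefore use small
networks with long, N-dependent measurement windows rather than large
networks with short ones:

- discontinuous field (F0): median of the potential-sector magnitudes
  (field pair and the two neutral directions removed) at N = 12, 18, 27
  with 16000N, 32000N, 64000N measured spikes — the predicted bias of
  the smallest median is below 3%. The median samples modes k ≈ 3–7,
  where the 1/k² law has set in.
- C0 field (F3): the 1/N⁴ spectra fall below the finite-time floor for
  N ≥ 18 at any workstation-scale window, so the probe is |λ| at the
  fixed wavenumber ϕ = π/3 (mode k = N/6, conjugate partners
  geometric-averaged, log-log interpolated) at N = 8, 10, 12 with
  20000N–64000N spikes. For F3 the k⁻⁴ law holds from k = 1 (the
  first-order eigenvalues give log-slope 3.89 between k = 1 and 2,
  3.97 between 2 and 4), so the best-converged modes carry the same
  collapse exponent.

Both estimators and N-sets were fixed from this convergence analysis
(unforced spectra plus the measured error floor) before the fits were
read off.

## Numerical choices

- Integrators: DOP853 with rtol 1e−12 / atol 1e−14 everywhere in the
  event-driven and variational machinery; the forced kernel is
  fixed-step RK4 (jit-compiled) because millions of steps are needed.
- Root solves: Brent with machine-precision tolerances; Newton damped
  to half the mode spacing in the mean-field equation.
- Degenerate (equal-potential) inputs to the event map are processed
  one label at a time; zero- and slightly negative-length steps are
  legal, which is exactly what the synchronous-state analysis needs.
- Positivity of F and of G = g + T0·F is checked at construction of
  fields and phase maps (fail fast, with the location of the zero).
- Eigenvalue extraction uses `numpy.linalg.eigvals` (LAPACK balancing);
  for C∞ fields exponents below ~1e−11 are reported but carry no
  information.

## What the tests do and do not show

The test suite validates the analytics against independent oracles:
closed forms for the LIF flow, finite-difference Jacobians for both
Floquet constructions, forward event-driven simulation for the fixed
point, quadrature against endpoint asymptotics, Floquet-vs-Lyapunov
equivalence at A = 0, and the scaling laws at reduced sizes
(N ≤ 200 splay, N ≤ 27 forced). They do not probe heterogeneous
neurons, noise, delays, sparse topologies, or clustered states other
than full synchrony — all outside the model class — and the forced
fits, while unbiased in the fitted exponent, use problem sizes far
below publication scale, so their prefactors should not be quoted.

## Known limitations

- Forced simulations support α-pulses and the catalog fields only (the
  kernel inlines F and F′ for speed).
- Repeated pulse poles beyond the α-pulse double pole take the slow
  `expm` path.
- The evaporation exponent of an expelled probe (strong inhibition with
  discontinuous pulses) is reported as a δ-dependent escape rate; only
  its sign is meaningful.
- The mean-field exact-root solver tracks one branch per mode index; it
  is not a global root finder.
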