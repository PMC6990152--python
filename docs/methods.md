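# Methods

This note records the models, numerical choices and design decisions
behind `hergtemp`, and what the package's tests do and do not establish.

## Kinetic model

I<sub>Kr</sub> is modelled as `g·a·r·(V − E_K)` with independent
Hodgkin–Huxley activation (`a`) and inactivation (`r`) gates. Each gate
relaxes mono-exponentially toward its voltage-dependent steady state;
the four transition rates are single exponentials in voltage,
`k = A·exp(B·V)`, as follows from a single-barrier transition-state
argument with a voltage-linear Gibbs energy. The nine parameters
{g, p1…p8} are strictly positive; the negative voltage dependence of the
backward rates is carried by the rate law (−p4, −p8 exponents), not by
signed parameters.

Units are the electrophysiology convention throughout: ms, mV, rates in
1/ms, voltage sensitivities in 1/mV; temperature is kelvin internally
and Celsius at user-facing interfaces. E_K comes from the Nernst
equation with CODATA 2018 constants; with the default solutions
(4/110 mM K⁺) it is −85.2 mV at 25 °C and scales linearly in absolute
temperature.

Closed forms are used for the derived quantities: V<sub>1/2</sub> =
ln(p3/p1)/(p2+p4); the time-constant maximum of a gate with rates
A₁e^{B₁V} + A₂e^{−B₂V} sits at V* = ln(A₂B₂/(A₁B₁))/(B₁+B₂). Grid
searches appear only as test oracles. Steady states are evaluated in
logistic (log-space) form, so no exponential overflow is possible; raw
rate evaluations clamp the exponent at ±700 with a warning — staircase
voltages never approach that, but optimizers may propose extreme
parameters.

## Simulation

Step protocols are integrated exactly: within a constant-voltage segment
each gate follows `x(t) = x_∞ − (x_∞ − x0)·e^{−t/τ}`, and the state is
chained across segments at the exact boundary times, independent of the
output grid. Sampling default is dt = 0.1 ms (typical patch-clamp
sampling); the analytic path is the workhorse for fitting and MCMC
(~1 ms per 15-s staircase evaluation at 1 ms sampling).

Ramps and sampled (action-potential-like) waveforms go through scipy's
LSODA via `solve_ivp`, segment by segment for step protocols so the
solver never crosses a discontinuity. Default tolerances are abs 1e-8 /
rel 1e-10. Gates are clipped to [0, 1] on output, warning if the
excursion exceeds 1e-6. The central simulator test cross-validates the
two paths on the fixture staircase: with abs_tol 1e-12 they agree to a
maximum relative current error below 1e-6 on all samples above 1e-6 of
the peak.

Protocol segments are half-open `[t_start, t_end)`, so the voltage at a
boundary is the new segment's value — the usual clamp-simulator
convention, and the one that makes voltage lookup deterministic.

The built-in staircase is this package's own documented fixture: 15 s
total, rungs covering −120 to +60 mV in 500 ms steps (ascending then
descending, each rung followed by a 60 mV drop), preceded by the
+40 → −120 mV activation/tail step that the tail-extrapolation
conductance estimate requires. The exact rungs of the published
calibration staircase are not reproduced; a real protocol can be loaded
from the step-protocol text format instead. Initial conditions for any
protocol are the steady states at the first segment's voltage
(pre-equilibration), since holding periods long relative to τ_a are
impractical to simulate by default.

## Synthetic data generator

The generator emulates a multi-well automated patch-clamp temperature
experiment:

* **Temperatures** 25, 27, 30, 33, 37 °C; solutions 4/110 mM K⁺.
* **Population structure** per temperature: well log-parameters
  φ_j ~ N(μ, Σ). Default Σ is diagonal with log-SD 0.1 on rate
  prefactors, 0.05 on voltage sensitivities and 0.2 on conductance —
  cell-to-cell expression varies far more than kinetics. Conductance is
  one coordinate of φ, making it lognormal and independent of the
  kinetics under the diagonal default.
* **Noise**: additive i.i.d. Gaussian current noise; the default SD is
  5% of each well's peak current (per-well absolute SDs are recorded in
  the ground truth).
* **Temperature dependence**: μ(T) follows a Generalized Eyring law per
  rate, so per-temperature population means lie *exactly* on Eyring-plot
  lines — the fixture that makes temperature-model fitting exactly
  recoverable. The fixture truth is anchored at 25 °C to representative
  room-temperature hERG magnitudes (τ_a of seconds, τ_r of milliseconds)
  with fold-changes per +10 K of 8 / 5 / 3.2 / 2.6 for k1…k4 — the
  activation pair far more temperature sensitive than the inactivation
  pair — and nonzero c_GE on every voltage sensitivity, so neither a Q10
  law nor the Typical Eyring restriction holds. These are documented
  fixture values, not fitted estimates.
* Conductance is temperature independent in the generator (its mean does
  not move with T).

Not emulated: leak and endogenous currents (an optional linear leak can
be added to stress inference, but quality control and leak/blocker
subtraction are out of scope), series-resistance and capacitance
artifacts, double-exponential deactivation (the two-gate model is the
data-generating model, so model discrepancy is absent by construction).
Passing recovery tests therefore demonstrate correctness of the
*inference machinery* under the assumed statistical model, not
robustness to the artifacts of real recordings.

Everything is reproducible: (truth, seed) determines the dataset
byte-for-byte, with per-well sub-seeds drawn from a single generator.

## Inference

Parameters are inferred as φ = ln θ under a uniform box prior (closed
bounds): prefactors 1e-7…1e3 /ms, sensitivities 1e-7…0.4 /mV,
conductance broad. The likelihood is the standard i.i.d. Gaussian form
with the (2πσ²)^{−N/2} normaliser.

**Point estimation** is multi-start bounded nonlinear least squares
(scipy `least_squares`, trust-region reflective) on the eight
log-kinetics. Two reductions make this robust: the conductance enters
the current linearly and is profiled in closed form inside every
residual evaluation, and σ is profiled as the RMS residual. Random
starts are drawn log-uniformly from a physiologically plausible sub-box
of the prior (prefactors 1e-6…1 /ms, sensitivities 1e-3…0.2 /mV),
rejecting starts whose simulated current is degenerate; ties break by
best penalised objective then start order. On noiseless fixture
staircase data, 10 starts recover all nine log-parameters to machine
precision; at 5% noise and 0.1 ms sampling the worst parameter error is
a few percent.

**Per-well MCMC** is an adaptive Metropolis chain on (φ, ln σ). The
proposal covariance is seeded from a Gauss–Newton (Laplace)
approximation at the MAP — σ̂²(JᵀJ)⁻¹ for φ, 1/(2N) for ln σ — scaled by
2.38²/d, then adapted Haario-style with a decaying learning rate
(offset so early adaptation refines rather than overwrites the seed) and
a global scale steered toward 23.4% acceptance. The first half of each
chain is burn-in; default thinning 10. Three jittered chains on a
staircase fixture reach split-R̂ < 1.05 within 8000 iterations. Short,
weakly informative protocols leave (p2, p3, p4) poorly identified and
mix slowly — a property of the posterior, not the sampler; the 15-s
staircase is what makes all nine parameters identifiable from one sweep.

**Hierarchical pooling** uses the simplified pseudo-Metropolis-within-
Gibbs scheme: each iteration draws one φ_j uniformly from every well's
pre-computed posterior sample pool, then performs the conjugate Gibbs
update of (μ, Σ) under a normal-inverse-Wishart hyperprior (ν₀ = 11 =
d + 2, Ψ₀ = 0.01·I, μ₀ at the prior-box midpoint, κ₀ = 1e-4 — weakly
informative; the resampling step is what lets well posteriors be reused
rather than re-simulated). With 30 synthetic wells the true μ falls
inside the 95% credible interval for all nine coordinates at the tested
seeds, and posterior-mean μ is unbiased across replicates within
Monte-Carlo error.

Since the study's original optimisation/sampling stack (CMA-ES and a
dedicated inference library) is not a dependency here, the optimizer and
samplers above are the package's own; the recovery and convergence tests
are the evidence that they are adequate for this model class.

## Temperature models

Per-temperature posterior samples of μ are transformed to the Eyring
plot: prefactor coordinates become ln(p/T) = φ − ln T, sensitivity
coordinates become p = e^φ; means and SDs are taken per temperature.
(Sensitivities are stored positive; plots conventionally show |B|.)

* **Generalized Eyring**: ordinary least squares of ln(A/T) on 1/T gives
  (ln a_GE, −b_GE); OLS of B on 1/T gives (c_GE, d_GE). Exact recovery
  to 1e-10 from noise-free lines.
* **Q10**: ln A = a_Q10·T + c_Q10 is linear in T, and the ln T term
  cancels from the Eyring-ordinate residuals, so the least-squares
  problem reduces exactly to OLS of ln A on T; Q10 = exp(10·a_Q10).
  B-type parameters are constant under Q10 and are anchored to their
  mean and SD at T_ref = 298.15 K (25 °C), the standard way Q10
  extrapolations are used from room temperature.
* Mean and SD series are fitted independently with identical functional
  forms, unweighted (no weighting scheme is singled out by the data
  model; the SD fit only feeds uncertainty bands).
* **Typical Eyring** is the d_GE = 0 restriction; its tenability is
  assessed per rate by whether 0 lies in the 95% t-based confidence
  interval of the OLS intercept (≥ 3 temperatures required). 95% is the
  package's choice of conventional level.
* **Physical reading**: ΔS = R·ln(a_GE·h/k_B) (rates converted to 1/s),
  ΔH = R·b_GE, z_e = c_GE·R/F (per volt), D = d_GE; the mapping
  round-trips exactly.

A printed-form ambiguity in the Q10 Eyring-ordinate expression was
resolved to ln(A/T) = a_Q10·T + ln(1/T) + c_Q10 — the unique form
consistent with ln A affine in T.

## Q10 protocol-dependence study

`estimate_q10` reproduces how Q10 coefficients are measured in practice:
simulate a probing protocol at two temperatures, extract a time constant
by exponential fitting of a named trace segment, and form
Q10 = (τ_cold/τ_hot)^{10/ΔT}. Two editable spec families approximate the
two classical experiment styles (activation as the current rise during a
long 0 or +40 mV step; deactivation as tail decay at −50 or −70 mV;
inactivation onset at +40 or +60 mV after a brief −120 mV recovery
interval; recovery as the rising tail hook at −120 or −90 mV, fitted
only up to the hook's peak since the later decay follows the activation
gate). Exponential fits are single-exponential nonlinear least squares
initialised from a log-linear regression of the detrended segment; a
double-exponential option exists.

Because each probe reads the rate at a different voltage, and the
fixture's voltage sensitivities B change with temperature, the two spec
families disagree (activation estimates differ by ~13%) and neither
matches the direct fit — the protocol dependence the machinery exists to
expose. When the rates are scaled uniformly (a pure Q10 world) all
estimators agree with the generating Q10 to within the ~5% tolerance of
mono-exponential summaries of two-gate currents.

## Normalisation procedures

For visual comparison of wells, traces can be scaled to a reference
(closed-form least squares by default; an absolute-difference mode via
1-D minimisation), or put on a conductance scale by fitting a single
exponential to the early tail current after the +40 → −120 mV step,
extrapolating back to the step instant, and dividing by the driving
force under the a ≈ 1 approximation. The estimate is accurate to ~1%
when the depolarising step is long enough to saturate activation and
inactivation recovers fully at −120 mV; with the 500 ms leading step of
the fixture staircase it is biased low by ~15% (activation has not
saturated), which is why validation uses unnormalised currents with
per-well conductances.

## Problem sizes and defaults

The shipped tests and the acceptance script run at reduced but
representative sizes chosen as a sensible desk-scale study: single-well
recovery on the full 15-s staircase (0.1–1 ms sampling); hierarchical
recovery with 30 wells at 1 ms sampling, one 3000-iteration chain per
well and 4000 pseudo-MwG iterations; convergence diagnostics with
3 × 8000-iteration chains. Library defaults are larger (3 × 20000
iterations, thinning 10) and match what one would use on real data.

## Known limitations

* The hierarchical stage reuses fixed per-well sample pools; very narrow
  pools understate μ uncertainty relative to a full joint sampler.
* Exponential-fit Q10 summaries carry a few-percent method bias on
  two-gate currents even when the Q10 law holds exactly.
* The Typical-Eyring assessment treats the per-temperature means as
  independent observations; with few temperatures its power is limited.
* Fits assume the two-gate structure is the true data-generating model;
  none of the tests probe structural misspecification.
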