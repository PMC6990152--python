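# hergtemp

Temperature dependence of hERG (Kv11.1) channel kinetics: simulation,
hierarchical Bayesian inference, and Eyring/Q10 temperature models.

## The problem

The hERG channel carries the rapid delayed-rectifier potassium current
I<sub>Kr</sub>, the main target of drug-safety screening. Screens are
usually run at room temperature, while predictions are needed at body
temperature, so results are extrapolated — classically with a Q10
coefficient (a fixed fold-change in rate per 10 °C) or with Eyring rate
theory. Whether those extrapolations are faithful is an empirical
question: one can fit a kinetic model to voltage-clamp recordings at
several temperatures and ask whether the fitted rate parameters actually
follow a Q10 or Eyring law.

`hergtemp` implements that analysis as a tested pipeline for anyone who
wants to run it on their own multi-well patch-clamp data or study its
statistical behaviour on synthetic data:

* a two-gate Hodgkin–Huxley hERG model with exact (piecewise-analytic)
  and stiff-ODE simulators for arbitrary voltage-clamp protocols;
* a synthetic-data generator with the full statistical structure the
  inference assumes (per-well lognormal parameter variability, additive
  Gaussian current noise, Eyring-governed temperature dependence);
* per-well maximum-a-posteriori fitting and adaptive-Metropolis MCMC,
  pooled across wells with a pseudo-Metropolis-within-Gibbs hierarchical
  model;
* Eyring-plot transforms and least-squares fitting of Generalized
  Eyring, Typical Eyring and Q10 temperature models, with physical
  (entropy/enthalpy/valency) interpretation;
* a simulator of classical Q10-estimation experiments that demonstrates
  the protocol dependence of Q10 estimates.

## The model

Current is Ohmic with two independent gates,

    I_Kr = g · a · r · (V − E_K),

where `a` (activation, slow) and `r` (inactivation, fast) relax as
`dx/dt = (x_∞ − x)/τ_x`, with steady states and time constants set by
four voltage-dependent transition rates

    k1 = p1·exp(p2·V)    k2 = p3·exp(−p4·V)     (activation pair)
    k3 = p5·exp(p6·V)    k4 = p7·exp(−p8·V)     (inactivation pair)

giving nine positive parameters θ = {g, p1…p8} per cell. Each rate has
the thermodynamic form k = A·exp(B·V). On an *Eyring plot* — ln(A/T)
and B against 1/T — the candidate temperature models are:

| model              | ln(A/T)                  | B                    |
|--------------------|--------------------------|----------------------|
| Generalized Eyring | ln a_GE − b_GE/T (line)  | c_GE/T + d_GE (line) |
| Typical Eyring     | same line                | c_GE/T (via origin)  |
| Q10                | ln Q10·T/10 + … (curve)  | constant             |

The prefactor curves are practically indistinguishable within 22–37 °C;
only the voltage-sensitivity parameters B discriminate the theories.

Inference works on φ = ln θ with a uniform box prior and i.i.d. Gaussian
current noise; wells at one temperature are pooled hierarchically,
φ_j ~ N(μ, Σ), and the temperature models are fitted to the mean and SD
of μ(T) on the Eyring plot by linear least squares.

## Worked example

```python
import numpy as np
import hergtemp as ht

truth = ht.default_temperature_truth()          # fixture Eyring ground truth
cold = ht.parameters_at_temperature(truth, ht.celsius_to_kelvin(25.0))
hot = ht.parameters_at_temperature(truth, ht.celsius_to_kelvin(37.0))

for label, p in (("25 C", cold), ("37 C", hot)):
    v_half = ht.half_activation_voltage(p)
    _, tau_a = ht.tau_peak(p, "activation")
    _, tau_r = ht.tau_peak(p, "inactivation")
    print(f"{label}: V1/2 = {v_half:6.1f} mV   "
          f"max tau_a = {tau_a/1000:5.2f} s   max tau_r = {tau_r:5.2f} ms")

protocol = ht.builtin_protocol("staircase-fixture")
cond = ht.IonicConditions.at_celsius(25.0)
pop = ht.hierarchical_truth_at(truth, 25.0, log_sd=np.zeros(9))
well = ht.generate_dataset(pop, protocol, 1, seed=7, dt=0.5).wells[0]
fit = ht.fit_well(well.trace, protocol, cond, n_starts=6, seed=42)
rel = np.abs(fit.params.as_vector() / well.params.as_vector() - 1)
print(f"refit at 5% noise: worst parameter error = {100*rel.max():.1f}%")

ests = [ht.estimate_q10(cold, hot, spec)
        for specs in (ht.zhou_style_specs(), ht.vandenberg_style_specs())
        for spec in specs.values()]
from hergtemp.temperature import series_from_ge_coefficients
series = series_from_ge_coefficients(truth.a_ge, truth.b_ge, truth.c_ge,
                                     truth.d_ge,
                                     [ht.celsius_to_kelvin(t)
                                      for t in ht.DEFAULT_TEMPERATURES_C])
print(ht.build_q10_report(ests, ht.fit_q10(series)).round(2))
```

prints

```
25 C: V1/2 =  -15.1 mV   max tau_a =  6.40 s   max tau_r = 12.61 ms
37 C: V1/2 =  -21.0 mV   max tau_a =  0.73 s   max tau_r =  3.35 ms
refit at 5% noise: worst parameter error = 8.5%
              zhou  vandenberg  direct-fit
process                                   
activation    7.52        6.64        7.89
deactivation  4.40        4.10        4.95
inactivation  2.90        2.92        3.18
recovery      2.61        2.74        2.58
```

Reading the output: warming from 25 to 37 °C shifts half-activation
negative, collapses the activation time constant from seconds toward
hundreds of milliseconds and speeds inactivation about fourfold —
activation is far more temperature sensitive than inactivation. A single
noisy staircase recording suffices to refit all nine parameters. The
final table is the package's protocol-dependence study: two simulated
classical experiments ("zhou"- and "vandenberg"-style protocols) applied
to the *same* underlying kinetics give Q10 estimates that disagree with
each other (13% apart for activation) and with the direct fit to the
parameter temperature dependence — and most estimates fall outside the
conventional Q10 ∈ [2, 3] range.

A command-line pipeline wraps the same stages:

```
hergtemp generate --out data            # synthetic multi-temperature dataset
hergtemp fit data --out posteriors      # per-well MCMC + hierarchical pooling
hergtemp fit-temperature posteriors --out fits
hergtemp q10-study cold.json hot.json --out q10
```

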