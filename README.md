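# cardioemu

Gaussian-process emulation, uncertainty analysis and variance-based
sensitivity analysis of the Luo–Rudy 1991 (LR1991) ventricular
action-potential model.

## The problem

Cardiac cell models are stiff, nonlinear ODE systems with many
parameters whose values are never known exactly. Understanding how
parameter uncertainty propagates into model outputs normally requires
thousands of simulator runs. This package takes the surrogate-model
route: it treats the cell model as a deterministic *simulator*
**y** = *f*(**x**) mapping six maximum ionic conductances
(G_Na, G_si, G_K, G_K1, G_Kp, G_b — channel/pump densities, mS cm⁻²)
to eight scalar outputs describing the action potential and its
restitution, and fits one *Gaussian-process emulator* per output from a
small set of simulator runs. Once fitted, the emulators give analytic
(no-further-simulation) answers to uncertainty and sensitivity
questions. The intended audience is cardiac/systems-biology modellers
who want calibrated surrogate-based UQ rather than brute-force Monte
Carlo.

The eight outputs: maximum upstroke velocity max dV/dt, peak V, plateau
dome V, APD₉₀, resting V, APD₅₀ (measured on the final beat of a train
of nine S1 stimuli, −25.5 µA cm⁻², 2 ms, cycle length 1000 ms), plus the
maximum slope of the APD-restitution curve and the minimum diastolic
interval, obtained from an S1–S2 protocol. Restitution curves are
summarised by the exponential fit

&nbsp;&nbsp;&nbsp;&nbsp;APD(DI) = a − b·e^(−DI/c),

whose slope at the minimum captured DI, (b/c)·e^(−DI_min/c), is the
restitution-slope output.

## The statistical model

Each output gets a GP prior with a linear mean and Gaussian
(squared-exponential) covariance,

&nbsp;&nbsp;&nbsp;&nbsp;f(x) ~ GP( h(x)ᵀβ, σ² c(x,x′) ),
&nbsp;&nbsp;h(x) = (1, x₁,…,x₆)ᵀ,
&nbsp;&nbsp;c(x,x′) = exp(−Σⱼ ((xⱼ−x′ⱼ)/δⱼ)²),

with the weak prior p(β, σ²) ∝ σ⁻². β and σ² are marginalised
analytically; the correlation lengths δ (and a small noise nugget) are
set to the mode of their concentrated log posterior. Training inputs are
a 200-point Latin hypercube over each conductance's nominal ±25% range,
normalized to [0,1]; 20 further runs are held out for validation via
standardized errors and the Mahalanobis distance, whose reference
distribution has mean m and variance 2m(m+n−q−2)/(n−q−4) for m test
points, n design points and q = 7 mean-function regressors. With
independent normal inputs (normalized mean 0.5, variance 0.04), the
output mean/variance, mean-effect curves E[f(x)|x_w] and main-effect
(first-order Sobol) indices Var[E{f(x)|x_w}]/Var[f(x)] are all evaluated
in closed form. A NIPALS partial-least-squares regression of the eight
outputs on the six inputs provides the comparison baseline.

## Worked example

```python
from cardioemu import (Conductances, run_s1_protocol, extract_ap_biomarkers,
                       restitution_protocol, fit_restitution)

g = Conductances()                       # published nominal conductances
trace = run_s1_protocol(g)               # nine S1 beats, returns the last
bm = extract_ap_biomarkers(trace)
print(f"APD90 {bm.apd90:.1f} ms, APD50 {bm.apd50:.1f} ms, "
      f"peak {bm.peak_v:.1f} mV, max dV/dt {bm.max_dvdt:.0f} mV/ms")

curve = restitution_protocol(g, s1_trace=trace)
fit = fit_restitution(curve)
print(f"restitution: a={fit.a:.1f} b={fit.b:.1f} c={fit.c:.1f} "
      f"max slope {fit.max_slope:.2f} at DI_min {curve.min_di:.1f} ms")
```

prints

```
APD90 363.5 ms, APD50 323.5 ms, peak 47.0 mV, max dV/dt 416 mV/ms
restitution: a=356.8 b=168.7 c=90.3 max slope 1.70 at DI_min 8.5 ms
```

i.e. a normal LR1991 action potential (~360 ms APD₉₀ at 1 Hz pacing) and
a restitution slope above 1, the classical alternans threshold. The full
study — design generation, emulator fitting, validation, UA/SA and the
PLS baseline — runs end to end with

```bash
cardioemu pipeline --design-n 200 --test-n 20 --seed 0 --outdir out/
```

which writes the datasets, serialized emulators, a validation report and
a summary table (per output: design mean, emulator mean, its variance,
coefficient of variation, Mahalanobis distance). Individual stages are
exposed as `cardioemu simulate | design | fit | validate | ua | sa | pls`.

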