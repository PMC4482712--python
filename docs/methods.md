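# Methods

This note documents the models, algorithms and numerical choices behind
`cardioemu`, in the package's own words: what is computed, under which
assumptions, and where the design was genuinely open.

## 1. The cell simulator

The simulator is the Luo–Rudy 1991 guinea-pig ventricular cell model:
eight state variables (membrane potential V; Hodgkin–Huxley gates m, h,
j for the fast sodium current, d, f for the slow inward calcium
current, X for the time-dependent potassium current; intracellular
calcium Ca_i) and six membrane currents I_Na, I_si, I_K, I_K1, I_Kp and
a linear background current I_b. Rate equations, reversal potentials
(RT/F = 26.71 mV at 310 K) and the published initial state follow the
original model formulation as encoded in its standard CellML
transcription. Each current is exactly linear in its maximum
conductance; the six conductances are the model inputs, with nominal
values (23, 0.09, 0.282, 0.6047, 0.0183, 0.03921) mS cm⁻². The stimulus
convention is that a negative applied current density depolarises
(dV/dt = −ΣI/C_m, C_m = 1 µF cm⁻²), so the study stimulus of
−25.5 µA cm⁻² for 2 ms elicits a beat.

### Integration scheme

Production runs use a fixed-step Rush–Larsen scheme: gating variables
are updated exactly for frozen V (y ← y_∞ + (y−y_∞)e^(−Δt/τ), which is
unconditionally stable for the stiff gate equations), while V and Ca_i
take a forward-Euler step. Two step sizes are used — 0.002 ms in a
10 ms window after each stimulus onset (the upstroke, where dV/dt
reaches ~400 mV/ms and τ_m ~ 10 µs matters), 0.05 ms elsewhere — and
the state is recorded every 0.1 ms. The inner loop is numba-compiled;
one nine-beat S1 train costs ~0.1 s, which is what makes per-design
restitution scans and whole-design regeneration tractable.

An implicit BDF path (scipy, rtol 10⁻⁶, atol 10⁻⁸, max step 1 ms) is
kept as an independent accuracy reference; the test suite checks that
both paths agree on the biomarkers (APD₉₀ within 1 ms, peak V within
0.5 mV). Spot checks against LSODA at rtol 10⁻¹⁰ put the Rush–Larsen
APD₉₀ error below 0.1 ms and the instantaneous max-dV/dt error below
0.2%.

Because a 0.1 ms sampling grid systematically underestimates the
upstroke velocity (finite differences give ~379 mV/ms where the true
instantaneous maximum is ~416 mV/ms at nominal inputs), the integrator
tracks the maximum instantaneous dV/dt at substep resolution and the
biomarker layer reports that quantity.

## 2. Biomarkers

Six outputs are measured on the final S1 beat:

* resting V — the voltage immediately before the final stimulus;
* max dV/dt — instantaneous, as above;
* peak V — the maximum after the upstroke (the sodium spike);
* dome V — the plateau maximum, defined as the maximum of V over the
  window from 20 ms after the upstroke to the provisional
  (peak-referenced) 50%-repolarisation crossing. The 20 ms offset
  excludes the spike; the window end keeps the search inside the
  plateau for short action potentials.
* APD₉₀ / APD₅₀ — time from the instant of maximum dV/dt to the first
  downward crossing of V_thr = dome − f·(dome − rest), f = 0.9/0.5,
  with linear interpolation between samples.

Repolarisation thresholds are referenced to the **dome**, not the
spike peak. The two conventions differ by ~60 ms in APD₅₀ (the spike
inflates the amplitude on which the fraction is taken); dome-referenced
thresholds are what reproduce the published design-mean APD₅₀/APD₉₀ of
this protocol, and the spike is an upstroke artifact rather than part
of the repolarisation trajectory. A `reference="peak"` option retains
the other convention.

### Restitution protocol

From the stored end-of-train state, each S2 run re-delivers one S1
stimulus at t = 0 (by near-periodicity this reproduces the steady beat)
and an S2 stimulus at the coupling interval. Couplings start at the S1
cycle length and shrink in 10 ms steps until the S2 beat fails the
capture criterion APD₉₀ > 100 ms; the failure edge is then refined in
1 ms steps, so the minimum DI is resolved to 1 ms (reported minimum-DI
statistics are scan-resolution dependent). Each retained beat
contributes a point (DI, APD₉₀) with DI = coupling − APD₉₀(steady S1
beat); the S1-based DI convention is standard and stable. The curve is
fitted with APD(DI) = a − b·e^(−DI/c) by Nelder–Mead least squares
(three starting points around (max APD, APD span, 50 ms), with a polish
restart from the incumbent; c ≤ 0 is rejected by penalty). The
maximum restitution slope is the fitted curve's derivative at the
minimum DI, (b/c)·e^(−DI_min/c). A printed form of this quantity
circulates with b in the denominator of the exponent; that form is
dimensionally inconsistent with being the slope of the fitted curve,
and the derivative is what is implemented.

## 3. Design data

Inputs are sampled by Latin hypercube (one point uniformly placed in
each of n strata per coordinate, random column permutations — scipy's
scrambled LHS) over nominal ±25% in each conductance, then mapped
affinely to [0,1]⁶ with the nominal values at 0.5. The study sizes are
200 design + 20 test runs; both are regenerated by seed, and datasets
are stored as plain CSV with six input and eight output columns.
Natural-scale tables of the sensitivity-analysis distribution imply a
different normalized variance than the normalized-scale statement
(0.0064 vs 0.04); the normalized scale is treated as canonical
(N(0.5, 0.04) per input, independent) and the natural-scale variances
as erroneous.

Runs that fail (no capture, censored repolarisation, solver failure)
are logged and excluded; more than 5% failures aborts, since that
indicates a protocol or range fault rather than bad luck. Restitution
scans can be restricted to the first k design rows
(`restitution_n=k`); the remaining rows carry NaN in the two
restitution columns and downstream consumers fit on complete rows.

## 4. The Gaussian-process emulator

One emulator per output, in the standard computer-experiment
formulation: linear mean h(x)ᵀβ with h(x) = (1, x₁,…,x₆)ᵀ (q = 7),
Gaussian correlation c(x,x′) = exp(−Σ((xⱼ−x′ⱼ)/δⱼ)²), weak prior
p(β, σ²) ∝ σ⁻². For fixed δ, β̂ is generalised least squares, and
σ̂² = residᵀA⁻¹resid/(n−q−2) (the Student-t scale). δ is estimated by
maximising the concentrated log posterior
−½[(n−q)·log σ̂² + log|A| + log|HᵀA⁻¹H|] over log δ with L-BFGS-B,
bounds δ ∈ [0.03, 30] on the unit cube, 10 starts (all-ones plus
seeded Latin-hypercube draws in log space), ties broken toward the
smallest ‖log δ‖. The posterior predictive is Student-t with n−q
degrees of freedom; at n−q ≈ 200 it is treated as Gaussian.

**Noise nugget.** By default a relative nugget is estimated jointly
with δ (same objective, bounds [10⁻¹², 1]). The simulator is
deterministic but its outputs carry ~0.05–0.1 ms of numerical texture
(integration grid, threshold interpolation, scan resolution), and a
strictly noise-free GP with plug-in δ is overconfident out of sample:
on regenerated 200/20-run datasets the fixed-nugget (10⁻⁸) APD₉₀
emulator gives Mahalanobis distances far above the reference band
(~80), while the estimated-nugget fit (typically ~10⁻⁶·σ̂², i.e. a
noise SD of ~0.1 ms) is calibrated (MD ~ 18–28, standardized errors
within ±2). A fixed-nugget mode (with ×10 escalation on factorisation
failure, capped at 10⁻⁴) remains available and is used by the
interpolation tests, where predictive variance at design points
collapses to the ~2·nugget·σ² floor.

Emulators serialize to JSON (hyperparameters + design data);
deserialization rebuilds the cached Cholesky factors without
re-optimisation.

## 5. Validation

Pointwise: standardized errors (y − μ*)/σ* on held-out runs. Joint:
the Mahalanobis distance MD = rᵀΣ*⁻¹r under the full m×m predictive
covariance (a diagonal variant is exposed as a diagnostic only). When
the emulator is adequate, MD follows the scaled-F reference
m(n−q−2)/(n−q)·F(m, n−q), with mean m and variance
2m(m+n−q−2)/(n−q−4); for (m, n, q) = (20, 200, 7) this is mean 20,
SD 6.68 (a value of 6.8 circulates from coarser rounding). The pass
flag is MD within mean ± 2 SD.

A caveat established empirically (ten regenerated design/test
replicates): the single-draw MD is heavy-tailed. Rare Latin-hypercube
test points land in the joint corner of the cube (G_si high, G_K and
G_K1 low) where APD₉₀ steepens towards the prolonged-repolarisation
regime just outside the design range, and a stationary GP is locally
overconfident there (a single point can contribute |z| ~ 10 and push
MD to ~140 while the other 19 errors are calibrated). The replicate
median MD is ~26. Validation conclusions should therefore rest on the
error pattern, not a single MD draw — which is how the acceptance test
is written.

## 6. Uncertainty and sensitivity analysis

Inputs are modelled as independent normals on the normalized scale
(default N(0.5, 0.04) per input; "effectively fixed" inputs use
variance 10⁻⁴). For this measure and the squared-exponential kernel,
every required integral factorises into one-dimensional Gaussian
integrals with closed forms; the package evaluates

* E*[E{f(X)}] and Var*[E{f(X)}] — the emulator mean of the output mean
  and the posterior (code) uncertainty about it;
* E*[Var{f(X)}] — the expected output variance, and the coefficient of
  variation √E*[Var{f}]/E*[E{f}];
* mean-effect curves M_w(s) = E*[E{f(x) | x_w = s}];
* main-effect indices Var[M_w(x_w)] / Var[E*{f(x)}].

The indices use the posterior-mean surface in both numerator and
denominator (plug-in), so an exactly additive surface yields indices
summing to one and the shortfall from one is a pure interaction
measure; the posterior-variance contribution that the full UA reports
separately is not mixed into the ratio. Every closed form is unit-tested
against Monte Carlo through the emulator (3-SE agreement), and the
emulator-propagated output distribution is checked against a direct
simulator Monte Carlo at reduced n.

The normal input measure is not truncated to [0,1] in the analytic
integrals (variance 0.04 puts ~1.2% of mass per tail outside); the
simulator Monte Carlo oracle truncates only at physical positivity.
This is a deliberate modelling approximation.

Input-uncertainty sweeps (e.g. widening the G_K distribution through
SD 0.01/0.02/0.05/0.1 while fixing the others) use the same machinery;
the natural-scale conversions of those settings equal SDs, not
variances, and are treated as such.

## 7. PLS baseline

The comparison emulator regresses the eight outputs on the six inputs
with NIPALS partial least squares: per component, scores are iterated
to 10⁻¹⁰ starting from the maximal-variance response column, X and Y
are deflated by the score regression, and coefficients are
W(PᵀW)⁻¹Qᵀ. With all six components and well-conditioned inputs this
equals ordinary least squares, which the tests assert, along with
agreement with an independent SVD-based PLS and with scikit-learn.
Before regression, APD₉₀ and max dV/dt are log-transformed in natural
units and all columns are then Z-scored — log before Z-scoring,
because Z-scores can be negative. The retained-component count
defaults to 6 (full rank).

## 8. Synthetic data and what the tests show

The simulator itself is the data generator; there is no external data.
Its defaults are the study conditions (nine S1 beats at 1000 ms,
−25.5 µA cm⁻² / 2 ms stimuli, 200/20-point designs, N(0.5, 0.04)
analysis distribution). The restitution-bearing statistics are
computed on a 50-point design, a size at which the design-mean
restitution slope is stable to well within the acceptance bands.
What passing tests show is internal consistency and faithfulness to
the published statistical pipeline on this model; they do not show
that the LR1991 model (a 1991-era, guinea-pig, single-cell
formulation) represents real cardiac tissue, nor that conclusions
transfer to biophysically detailed models whose outputs may be less
smooth in their parameters.

## 9. Known limitations

* Stationarity: a single Gaussian kernel cannot represent the local
  steepening of APD near the low-G_K corner; see §5.
* The minimum-DI output inherits a capture-threshold discontinuity and
  is both scan-resolution dependent and interaction-dominated; its
  emulator is the weakest of the eight.
* Main-effect indices only; total-effect (Sobol total) indices are out
  of scope, with 1 − Σ indices serving as the interaction diagnostic.
* The analytic UA/SA requires the product-normal input measure; other
  distributions fall back to Monte Carlo through the emulator.
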