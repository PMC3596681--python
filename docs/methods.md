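# Methods

## The deviation model

The package models the GTT response with two coupled linear ODEs in the
deviations of blood glucose `g(t)` [mg/dL] and plasma insulin `i(t)`
[µU/mL] from their fasting baselines:

    dg/dt = -p1·g - p2·i
    di/dt = -p4·i + p3·g

All four rate constants are strictly positive, encoding the physiological
feedback structure: both hormones self-clear (`-p1`, `-p4`), insulin lowers
glucose (`-p2`), and glucose stimulates insulin secretion (`+p3`).  The
glucose bolus that starts the test is a Dirac impulse at t = 0 and is
absorbed into the initial condition `g(0)`; for t > 0 the system is
unforced.  Simulation and fitting take the first observed sample as the
initial condition (for the embedded measurement set, (80, 0)).

Working in deviations rather than absolute concentrations removes the two
baseline nuisance parameters and makes the equilibrium the origin.  Times
are minutes internally — the parameter magnitudes (~1e-2 to 1e-3) are
per-minute rates — and hour-stamped inputs are converted on ingestion.

Eliminating `i` yields a damped harmonic oscillator for `g` (and,
identically, for `i`):

    g'' + 2α·g' + ω₀²·g = 0,    α = (p1+p4)/2,    ω₀² = p2·p3 + p1·p4

with the usual three regimes by the sign of α² − ω₀² (under/critical/over
damping).  Since exact equality is measure-zero in floating point, critical
damping is declared within a relative band |α² − ω₀²| ≤ 1e−12·max(α², ω₀²).
In the under-damped regime the closed form

    y(t) = e^{-αt}(c1·cos ωt + c2·sin ωt),   ω = sqrt(ω₀² - α²),
    c1 = y(0),   c2 = (y'(0) + α·y(0))/ω

is exact for both channels (initial slopes from the first-order system) and
serves as the analytic oracle against which the numerical integrators are
tested.

### The diagnostic period

The reported period is the *undamped* one, T = 2π/ω₀, not 2π/ω.  The
damped-oscillation amplitude shrinks but its period does not change, and
the undamped convention is what reproduces the published period values;
both subjects in the embedded data are firmly under-damped so the two
differ by <1% there anyway.  The diagnostic call is `normal` iff
T < 240 min, with a strict inequality (T exactly at the threshold counts as
diabetic); the threshold is exposed as a parameter.

### Bergman minimal model

The minimal model of glucose kinetics (glucose effectiveness S_G, remote
insulin-action compartment X(t) driven by plasma insulin above basal) is
included as a second RHS for simulation studies only.  No fitting machinery
is attached to it: estimating its parameters from real IVGTT insulin
profiles is a different experimental design and out of scope here.

## Integration

Fixed-step Euler, midpoint RK2 and classical RK4 on a uniform grid, final
step shortened to land exactly on the end time; states are interpolated
linearly between grid points when an observation falls off the grid.  The
default is RK4 at h = 0.1 min, which puts the discretisation error near
1e-10 on these dynamics — negligible against measurement noise and every
tolerance asserted anywhere in the package.  The systems are tiny (two
states) and non-stiff at physiological rate magnitudes, so adaptive step
control would add machinery without accuracy.  Where the test suite fits
repeatedly it uses h = 1–2 min, which keeps the error at ~1e-6 — still
orders of magnitude below the quantities being asserted — at a fraction of
the cost; those are problem-size choices of this package's test design.

A state that becomes non-finite during integration raises an error carrying
the blow-up time rather than propagating NaNs.

## Objectives

Residuals are observation minus model, ordered all-glucose then
all-insulin, time-ascending; glucose and insulin residuals carry equal unit
weights by default.  No variance weighting is applied across the two
channels — their numerical ranges are comparable here (tens of mg/dL vs
tens of µU/mL) — but per-observation weights are accepted for users who
want scale balancing.

* **Single shooting** integrates once from the first sample over the whole
  span.  The first sample defines the initial condition and contributes an
  exactly zero residual, avoiding double counting.
* **Multiple shooting** partitions the span at every observation time into
  k = n−1 subintervals, restarts each from the *observed* (g, i) at its
  left endpoint, scores the endpoint error, and sums.  Pinning the local
  initial values to the data (rather than optimising them under continuity
  constraints, as in the full multi-point boundary-value formulation) is
  well-defined because both state variables are observed at every sample,
  and it keeps the objective derivative-free.  Because every subinterval
  restarts on the data, the objective stays finite even for parameter sets
  whose trajectory diverges over the full span — the practical failure mode
  of single shooting.

Both objectives accept a raw unvalidated parameter 4-vector in addition to
the validated parameter type: optimizers probe candidates whose feasibility
is their own concern, and an unstable candidate must be scorable.

## Parameter estimation

### Perturbation search

A derivative-free pattern search.  Each iteration perturbs every parameter
by Δp_j = δ·|p_j| (δ = 0.1 initially) and enumerates all 3^m combinations
of {−Δ, 0, +Δ} per coordinate — 3⁴ = 81 objective evaluations for this
model, 3⁵ = 243 for a five-parameter model.  The best strictly-improving
candidate becomes the new centre (ties break to the first candidate in
lexicographic (−, 0, +) order, for reproducibility); Δ is recomputed from
the new centre after every accepted move.  When a full enumeration fails to
improve, δ is halved (range reduction) and the enumeration repeats.

Termination: the search stops when a shrink cycle yields positive but
relatively negligible improvement (< 1e-8), when δ falls below 1e-6, or at
the iteration cap (500).  A cycle with *zero* improvement keeps shrinking
rather than stopping: the SSR surface of this model has a narrow curved
valley in which a coarse grid can stall several scales before progress
resumes, and the δ floor bounds the extra cost at a handful of
enumerations.  The SSR trace is non-increasing by construction.

Candidates with any non-positive coordinate are scored +∞ without an
objective call (the model's rates are positive by assumption; a documented
toggle disables this for unconstrained problems), and a candidate on which
the objective fails numerically is scored +∞ rather than aborting the
search.  The core search is fully deterministic — there is no randomness to
seed.

### Gauss–Newton comparator

Classical Gauss–Newton with a central finite-difference Jacobian of the
model predictions: p ← p + (JᵀJ)⁻¹Jᵀε.  It converges in a handful of
iterations from good starts but is fragile from poor ones; the package
surfaces the failures as distinct errors — a singular/ill-conditioned
normal matrix (condition number > 1e14), and divergence (SSR growing five
consecutive iterations) — rather than returning a silently wrong answer.
That fragility is precisely the motivation for the derivative-free search.

## Glycemic indices

* HOMA-IR = FPG·FPI/405 with glucose in mg/dL, or FPG·FPI/22.5 in mmol/L
  (the constants agree exactly: 405 = 22.5 × 18).
* HOMA-IS = 1/HOMA-IR and HOMA-β = 20·FPI/(FPG[mmol/L] − 3.5) follow the
  standard Matthews forms; QUICKI = 1/(log₁₀FPG[mg/dL] + log₁₀FPI) uses the
  standard base-10, mg/dL convention.
* Lability index: Σ (ΔGluc[mmol/L])²/Δt[h] over consecutive reading pairs
  of a week, counting only gaps between 1 h and 12 h; excluded pairs are
  dropped, never bridged, and grouped scoring never pairs readings across a
  group boundary.
* MAGE: over one day of ≥7 readings, turning points are found after
  collapsing plateaus and monotone runs; excursions are |peak − nadir|
  swings between consecutive turning points; those exceeding one sample SD
  (ddof = 1) of the day's readings qualify, the direction (rise or fall) is
  set by the first qualifying excursion, and qualifying amplitudes in that
  direction are averaged.  A day with no qualifying excursion returns a
  distinct no-excursion result (`None`), not zero.  Windowing is per
  calendar day; multi-day protocols with optional night readings vary
  between clinics, and the per-day window is the simplest defensible
  reading.

## Synthetic data

The generator draws the exact closed-form trajectory of a known parameter
set at the requested sample times and adds independent Gaussian noise per
channel (default SD 0: noise-free).  Gaussian, independent measurement
error is the assumption under which the least-squares objective is the
maximum-likelihood estimator, which makes the generator the right
null-model for testing the fitting machinery.  It deliberately does not
emulate features of real GTT data — meal effects, ultradian insulin
oscillations, assay-dependent heteroscedasticity, timing jitter — so
passing recovery tests demonstrates correctness of the estimation
machinery, not clinical validity of the model on any particular cohort.
Noise draws use numpy's seeded PCG64 generator; identical seeds give
bitwise-identical series across runs and platforms.

The default sample grid is the study protocol: four hourly samples
(0–3 h), with the bolus response (80, 0) as the initial deviation.
Recovery experiments in the test suite use this grid and a finer 16-point
variant over the same 3-hour span, for both published parameter regimes,
from ±20% perturbed starts.

## Numerical choices and edge cases

* Critical-damping band: relative 1e-12, as above.
* Perturbation deltas are floored at 1e-12 absolute so a coordinate at zero
  can still move when positivity is off.
* Gauss–Newton finite-difference steps: relative 1e-6 per coordinate,
  floored at 1e-8 absolute.
* CSV I/O is comma-separated, dot-decimal, UTF-8, header mandatory; floats
  are written with 17 significant digits and parsed with correctly-rounded
  conversion, so round-trips are bit-exact.  Parse errors name the file,
  column and 1-based line.
* The embedded measurement fixture returns fresh copies on every call.

## Limitations

* The model is linear; it cannot represent saturating insulin action,
  hepatic glucose production thresholds, or delayed secretory phases.  Its
  value is the two-constant summary (α, ω₀) and the period diagnostic, not
  trajectory realism at fine time scales.
* The period-threshold diagnosis is a single-number screen; the package
  reports it alongside the damping constants rather than as a clinical
  verdict.
* Multiple shooting here pins subinterval starts to observations, so
  heavy measurement noise propagates into the restarts; the classic
  free-initial-value formulation with continuity constraints is out of
  scope.
* The minimal model is simulation-only, as noted.
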