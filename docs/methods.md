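# Methods

## Model and assumptions

Protein expression is modelled as a linear first-order balance forced by
the mRNA profile,

    dP/dt = Sp·M(t) − Dp·P(t),

with both rates constant in time.  This is the standard steady-state
turnover hypothesis: synthesis proportional to instantaneous mRNA level,
degradation proportional to instantaneous protein level.  The model is
appropriate when (i) the mRNA profile is simple — a single rise or a
single peak settling into a plateau as the system reaches homeostasis,
(ii) the protein rise is sigmoid (well described by a logistic), and
(iii) the anterograde and retrograde fits agree.  Multiple mRNA peaks, a
missing plateau, or mode disagreement all suggest time-dependent or
multiple rates, for which this model is not sufficient.

Half-life is a pure function of the degradation rate, h = ln 2 / Dp.  By
convention the anterograde degradation rates feed the half-life summary;
this is an arbitrary choice, and retrograde rates should give similar
values whenever the internal-consistency check passes.

Units: times are hours everywhere inside the package (minute-denominated
files are converted on read), Dp is h⁻¹, and Sp is protein-A.U. per
mRNA-A.U. per hour.  Both signals are relative (arbitrary-unit)
measurements, so Sp's absolute value is only meaningful relative to the
chosen normalisations: rescaling the mRNA by c maps Sp to Sp/c, rescaling
the protein by c maps Sp to c·Sp, and Dp is invariant to both (verified
as an exact equivariance in the test suite).

## Numerical solution of the forced ODE

The anterograde solution uses classical fixed-step 4th-order Runge–Kutta
aligned to the dense mRNA grid (default 2-min steps), with M at
half-steps taken as the linear interpolant between neighbouring nodes.
Because the ODE is linear, each RK4 step reduces to an affine recurrence
P[i+1] = A·P[i] + b[i] whose coefficients are precomputed in vectorised
form; this makes a single integration O(n) with tiny constants, and it
makes the integrator's fixed point under constant forcing *exactly* the
analytical steady state Sp·M/Dp.  Against the closed form for constant
forcing the relative error on the 2-min grid is ~1e−12, far below the
1e−6 documentation threshold.  Coarse (step > 6 min) or non-uniform grids
trigger a warning but still integrate.

The default initial condition is P(t₀) = 0 (observation starts at
initiation of expression).  The logistic Bottom parameter is treated as
measurement background — residual autofluorescence for imaging data — and
is excluded from the kinetic state everywhere: the retrograde inversion
and the anterograde fitting target both use P − bottom.  The alternative
(treating Bottom as pre-existing protein) would add a decaying transient
Bottom·e^(−Dp·t); for data with near-zero Bottom the difference is
negligible.

## Logistic fitting

Each protein replicate is fitted with the decadic four-parameter logistic
P(t) = Bottom + Span / (1 + 10^((logEC50 − t)·HillSlope)) by
Levenberg–Marquardt least squares (tolerances 1e−10, at most 1,000
function evaluations), with time in hours as the x-variable.  The
self-starting initialisation takes Bottom = min, Span = range, logEC50 =
the first half-range crossing, and HillSlope = 4 / (width of the 10–90%
rise).  The natural parameters are K = Span, t_i = logEC50,
r = HillSlope·ln 10; the two parameterisations are identical curves (a
property test checks equivalence to 1e−10 on random draws).  The curve is
evaluated through a numerically stable sigmoid, so extreme arguments
cannot overflow.

No R² cut-off is enforced — there is no principled universal threshold —
but the goodness report carries per-replicate and mean R², convergence
flags, and flags any |Bottom| above 10% of Span as a background concern.
Non-convergence returns a flagged result rather than raising; flat series
raise, since a logistic fit of a constant is meaningless.

## Rate estimation and confidence intervals

Both fitting directions minimise an unweighted sum of squares on the
window grid (default 0–15 h at 2 min, i.e. 451 points) with
Levenberg–Marquardt, searching over (log Sp, log Dp) so the rates stay
positive without explicit bounds.  Initialisation uses the homeostasis
relation: Dp⁰ = r (the logistic rate sets the time scale) and
Sp⁰ = Dp⁰·K / M_plateau with the mRNA plateau taken as the mean over the
final 10% of the window.  Tolerances are 1e−10 with at most 500 function
evaluations; replicates are fitted independently (no pooling).

The anterograde target is by default the logistic reconstruction of the
protein minus its background offset, matching the protocol file layout in
which only (K, t_i, r) per replicate travel downstream; a raw trace can
be fitted instead by passing a time series.  The fit's initial condition
defaults to the target's value at the window start — this makes the
estimator exact on protein curves that are exactly logistic (which start
slightly above zero at t = 0) and is indistinguishable from p0 = 0 on
real-shaped data; p0 = 0 can be forced explicitly.

95% confidence intervals come from the asymptotic covariance
s²(JᵀJ)⁻¹ at the optimum, with the Jacobian mapped to the natural scale
by the chain rule and a Student-t multiplier at n − 2 degrees of freedom.
A numerically singular JᵀJ (condition number > 1e14) marks the fit
non-identifiable and returns unbounded intervals.  These intervals
quantify regression uncertainty only; the protocol's validity check
requires them to be much smaller than the between-replicate spread, which
the package operationalises as (median CI half-width) / (IQR of point
estimates) < 1 per parameter — the ratio is always reported, the
threshold is a declared heuristic.

Coverage calibration: t-based intervals assume independent homoscedastic
residuals, so the coverage simulation uses the generator's additive-noise
option (sd = 5% of the protein plateau) and raw-trace anterograde fits
with p0 = 0 (the simulated truth starts at zero; a noisy pinned initial
value would otherwise inject unmodelled error).  Measured coverage with
200 repeats sits at 93–97% per parameter across seeds.

## Diagnostics

* Mann–Whitney U (two-tailed) compares anterograde vs retrograde rate
  samples; exact enumeration is used for combined n ≤ 20 without ties,
  the tie-corrected normal approximation otherwise; significance level
  0.01 by default.
* mRNA shape screen: interior maxima count (prominence ≥ 10% of range)
  and a plateau flag (mean |slope| over the final 10% of the window below
  2% of range per hour).  Both thresholds are scale-invariant heuristics
  standing in for the protocol's visual checks, and are configurable.
* The combined verdict is monotone in failures: zero failed components →
  suitable, one → warning, two or more → unsuitable.

## Synthetic data

The generator emulates the worked study conditions rather than arbitrary
signals.  The mRNA is M(t) = M∞(1 − e^(−αt)) + A·t·e^(−βt): zero at
initiation, exactly one interior peak (near 1/β) when A > 0, plateau M∞.
Defaults — M∞ = 1, A = 1, α = 0.2 h⁻¹, β = 0.35 h⁻¹ — give a single
peak ≈1.5× the plateau near 3 h, the qualitative shape of a suitable
developmental mRNA course.  Protein replicates are exact RK4 solutions of
the model with per-replicate rates drawn lognormally (median-preserving)
around the truth (default Sp = 0.5, Dp = 0.12 h⁻¹, i.e. half-life
≈ 5.8 h), plus multiplicative Gaussian noise (default CV 5%, mimicking
fluorescence intensity noise; an additive option exists for calibration
studies).  Defaults use 10 replicates with 20% rate variability on a
0–15 h window at 2 min; everything is reproducible from the seed.

Two constructions serve different purposes:

* the forward route integrates the ODE against the pulse-plateau mRNA.
  Its protein output is *near*-logistic (R² ≥ 0.999 noiseless in the
  default regime) but not exactly logistic, so estimates obtained through
  the logistic reconstruction carry a small systematic bias relative to
  the generating truth (a few percent on Dp, more on Sp) — exactly the
  approximation a practitioner accepts on real data.  Raw-trace
  anterograde fitting on this route recovers the truth to optimizer
  precision.
* the self-consistent route takes an exactly logistic protein and defines
  the mRNA as its exact analytical retrograde image; the pair satisfies
  the ODE identically, and both fitting directions recover the generating
  rates to ~1e−5 relative.  This is the construction used for strict
  recovery checks across the rate grid Sp ∈ {0.1, 0.5, 2} × Dp ∈
  {0.05, 0.12, 0.5} h⁻¹.

What the generator does **not** emulate: fluorophore maturation lag,
photobleaching, autofluorescence drift, embryo staging offsets, or
non-stationary rates.  Passing tests on synthetic data therefore
demonstrate correctness of the estimation machinery under the model's
assumptions, not robustness to those real-world effects.

## Preprocessing choices

* Moving average: centred window, odd width required (centering is
  ambiguous for even widths), truncated at the series boundaries rather
  than padded — no data are fabricated at initiation or plateau, where
  levels matter most.
* Spline densification: natural (zero second derivative) cubic
  interpolating spline, evaluated on a uniform grid whose point count is
  span_minutes/dt + 1; interpolation is exact at the input nodes, no
  extrapolation is permitted, and negative interpolated values are
  clipped to zero with a warning (abundances are non-negative).
* Background subtraction interpolates the control onto the sample grid,
  clips negative differences to zero and reports the clip count.

## Problem sizes

Default analyses run on 451-point windows (0–15 h at 2 min); the grid
checks use the 1,441-point 48 h grid.  The test suite's simulations use
40–60 repeats for distributional checks and 200 repeats for coverage;
the acceptance script's coverage run also uses 200 repeats.  A full
suite-plus-acceptance run completes in well under a minute on one CPU.

## Known limitations

* Constant-rate assumption: regulated translation or degradation
  (time-varying Sp, Dp) violates the model; the diagnostics flag the
  symptoms but cannot repair them.
* The logistic description is an approximation for forward-model data;
  rates estimated through it inherit a shape-dependent bias (documented
  above).  When raw traces are available, raw-trace anterograde fitting
  avoids it.
* CIs are asymptotic and unweighted; heteroscedastic noise (e.g.
  intensity-proportional) makes them approximate.
* The decay-from-homeostasis variant (estimating turnover after blocking
  synthesis) is deliberately out of scope.
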