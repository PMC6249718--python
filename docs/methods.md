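# Methods

## Model

A cancer lineage accumulates somatic mutations as a counting process whose
instantaneous rate grows with the number of mutations already present:
dN/dt = a + bN, with `a` the rate of cells without mutations. Solving and
rewriting in terms of the rate itself gives the working form

    μ(t) = μ₀ e^{bt},   λ(t) = ∫₀ᵗ μ = (μ₀/b)(e^{bt} − 1),

with μ₀ (per day) the initial mutation rate and b (per day) the exponent;
b = 0 recovers the constant-rate model. Mutation counts are Poisson with
mean λ(t), so the fraction of cells with j mutations is p_j = λ^j e^{−λ}/j!,
and the time of the first j-mutated cell is t_j = ln(b·j/μ₀ + 1)/b under the
convention λ(t_j) = j. Two compartment ODE systems express the same
dynamics — one driven by the continuous μ(t), one with a constant rate per
mutation class — both truncated at a maximal class k that absorbs all
inflow. All internal time is in days (1 month = 30.4375 d, 1 year =
365.25 d); cohort rates of ~0.02 are only dimensionally sensible per day.

## Inferring (b, μ₀) from (N, μ̄)

Sequencing studies report the count N and the average rate μ̄ = N/t_N.
Averaging the cumulative intensity over the first N events under the
approximation λ_j/j = e^{−bN/μ̄} gives λ̄_N = (N+1)/2 · e^{−bN/μ̄} and the
implicit relation

    μ̄ = e^{−bN/μ̄} b(N+1)/2 + bN/(e^{bN/μ̄} − 1).          (*)

Two properties of the signed residual r(b) = RHS − μ̄ shape the solver:

1. **It has a genuine positive root.** The expansion is
   r(b) = b/2 − (5/12)·μ̄·x² + O(x³) with x = bN/μ̄, so r rises from zero
   with slope 1/2, peaks at O(μ̄²/N²), and crosses zero near
   b\* ≈ (6/5)·μ̄/N². `solve_b(mode="root")` (the default) brackets this
   sign change and polishes it with Brent's method.
2. **It is ill-conditioned as a data fit.** The peak of r is far below the
   precision at which average rates are reported (four decimals), so every
   b between 0 and roughly 2b\* reproduces the printed μ̄. `solve_b` always
   reports the largest tolerance-feasible b (default tol = 5e-5 per day,
   half a unit in the last printed digit) and a `conditioned` flag stating
   that the solution set is an interval. `mode="feasible"` returns the
   interval endpoint instead of the root.

The initial rate follows from μ₀ = μ̄ − e^{−bN/(2μ̄)}·b(N+1)/2 (variant
`eq11`, the headline definition, default) or with exponent bN/μ̄ (variant
`eq10`); the two printed forms differ by a factor of two in the exponent
and the package computes either, surfacing the variant in all outputs
rather than resolving the discrepancy silently. A third estimator
μ₀ = bN/(e^{bN/μ̄} − 1) satisfies the exact decomposition
μ̄_RHS = b·λ̄_N + μ₀ and is used in identity tests. The geometric rate mean
μ̄′ = b·λ̄_N + μ₀(eq11) is ≤ μ̄ with equality iff b = 0; with the eq10/eq6
estimator it would equal the RHS of (\*) and slightly exceed μ̄, which is
why the eq11 variant is the default there too.

Validity: (\*) is derived for small x = bN/μ̄. At cohort scale (N ≈ 30–50,
b ≈ 1e-5–3e-5, x ≈ 0.03) the approximation error at the true b is well
below the feasibility tolerance; at N ≈ 500 with the same b it is not, and
the end-to-end tests deliberately stay in the clinical regime.

## Survival regressions

Each rate (initial and average, per day) is regressed on survival from
diagnosis (months) by unweighted OLS; no unit rescaling is applied. Fits
are ranked by `error = sqrt(Σ(μᵢ − μᵢ\*)²)/mean(μ)` — the root of the
*summed* squared residuals scaled by the mean observed rate, dimensionless
and invariant under common rescaling of the rates. On the embedded cohort
both slopes are negative and the initial-rate error is strictly smaller;
those two qualitative facts, not the coefficient values, are the package's
asserted claims (the published coefficients are not recoverable from the
published table by OLS under any unit convention, a documented
inconsistency).

## Doubling-time model

The reference schedule for pancreatic tumour growth is piecewise linear:
one population doubling per 2.3 days until angiogenesis at day 53 (23
doublings), then one per 56 days for 23 further doublings (through day
1341). Its smooth replacement DB(t) = a·t/(K+t) is fitted by unweighted
nonlinear least squares (`scipy.optimize.curve_fit`, analytic model, start
(40, 60); self-fits recover parameters to 1e-8 from any reasonable start).

**Choice of fitting data.** The schedule is defined by the 46 doublings it
realizes, so the default fitting set is the 46 event points (t = 2.3j for
j = 1..23; t = 53 + 56(j−23) for j = 24..46), giving a = 40.20 doublings
and K = 63.72 days — within 1.3% and 2.7% of the published (40.74, 62.04),
whose exact fitting data were not stated. Sampling the curve at integer
days 1..1341 instead (`grid="daily"`) gives (44.94, 150.30), far from the
published values, because the dense slow-phase samples dominate the loss;
this grid is retained as an option but is demonstrably not what produced
the published fit. Both reconstructions are documented as such.

A patient's curve rescales the cohort curve by their inferred parameters,
DT(t) = (μ₀/μ̄₀)·e^{(b−b̄)t}·a·t/(K+t), with μ̄₀ and b̄ arithmetic means of
the per-patient estimates; at the cohort means DT ≡ DB exactly. Time in
DT is in days, the unit in which (a, K) were fitted.

**Size conversion.** Cumulative doublings map to size by growing 2^d cells
from one founder at 10⁹ cells/cm³ into a sphere whose diameter is reported
(one cell ≈ 12.4 μm). The published size table's conversion is unstated, so
this one is explicit configuration (`cells_per_cm3`, geometry) and the
published sizes are shipped as provenance-flagged fixtures for sensitivity
comparison, never asserted. Time-to-size inverts the strictly increasing
size curve by Brent bisection on [0, horizon]; a target below the one-cell
size returns 0 and an unreachable target raises.

## Simulator

Mutation events are a nonhomogeneous Poisson process with intensity μ(t).
Sampling is by exact inversion — partial sums of unit exponentials mapped
through λ⁻¹(y) = log1p(by/μ₀)/b — using a counter-based Philox generator
keyed on the seed. Correctness is checked with the time-rescaling theorem:
λ(event times) must be a unit-rate Poisson process (KS test on the gaps,
aggregated across seeds, α = 0.01).

Recovery maximises the NHPP log-likelihood Σ log μ(tᵢ) − λ(t_N). μ₀ is
profiled analytically (μ̂₀(b) = N/(t_N·exprel(b·t_N))), leaving a bounded
1-D search over b (|b| ≤ 1e-2/day); standard errors come from the central
finite-difference Hessian in (log μ₀, b) with a delta-method back-transform.
Study sizes used in the tests: 100 replicates of N = 500 events at
μ₀ = 0.02/day, b = 2e-5/day give a median relative error on μ₀ below 10%;
bias shrinks from N = 50 to N = 500.

## What the synthetic data do and do not show

The generator realizes exactly the assumed model: exponential intensity,
no cell death, no driver/passenger distinction, no selection, and an
observation window ending precisely at the N-th event. Passing recovery
tests therefore demonstrates internal consistency of simulator and
estimator, not robustness to the ways real cohorts violate the model
(inter-patient heterogeneity beyond (μ₀, b), measurement error in N,
survival-dependent censoring). The embedded cohort is seven patients; the
regression comparison on it is a fixed-design qualitative check, not an
inferential result.

## Numerical choices

* All b → 0 limits go through `exprel`/`log1p`/`expm1`; branch threshold
  |b·t| < 1e-12 where an explicit limit is needed. Overflow guards clip
  exponents at 700.
* ODE integration: `solve_ivp` LSODA, rtol = atol = 1e-10; conservation of
  Σp_j held to 1e-8 and agreement with the Poisson closed form to 1e-6 on
  the tested grids. The demo configuration for the constant-vs-exponential
  comparison (μ₀ = 1e-6, b = 3e-5, k = 8, p₀(0) = 1) uses μ = μ₀ as the
  constant-rate baseline; that baseline value is a documented guess.
* `solve_b` scans a 512-point grid on the bracket (default [0, 1e-2]) to
  locate the sign change and the feasibility boundary before polishing
  with Brent; tol defaults to half a unit in the fourth decimal.
* Tie-breaks: the feasibility boundary refinement keeps the grid point if
  |r| − tol does not change sign at grid resolution.

## Known limitations

* The average-rate relation degrades outside small bN/μ̄ (see above).
* (a, K) depend on the reconstruction of the fitting data; both shipped
  grids are reconstructions, and the event grid is preferred on the
  evidence above.
* The doublings→size conversion is a modelling convention; absolute sizes
  and times-to-size should be read only comparatively across conversion
  settings.
* Several published per-patient values are internally inconsistent at the
  source (initial-rate column, clone-time-at-diagnosis column, one worked
  arithmetic example); they are stored verbatim with provenance flags and
  excluded from all oracles.
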