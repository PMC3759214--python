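# Methods

## Model

The natural history of one patient is a marked Poisson process.  Time `t`
runs from the (unobserved) age `T` at disease onset.

**Primary tumor.**  `Φ(t) = exp(β₀ t)` for `t ≤ V−T` (so
`T = V − ln S/β₀`, with `S = S_v/c` the primary size at the start of
treatment, which requires `β₀ > ln S / V`), and
`Φ(t) = S·exp(β₁ (t−(V−T)))` after.  `β₁ = −∞` encodes a non-recurrent
resected primary (`Φ = 0` after `V`).

**Shedding, viability, latency.**  Metastases are shed with Poisson
intensity `α Φ(t)^θ`.  `θ = 1` means every cell sheds; `θ = 2/3` surface
shedding; `θ = 0` a stable metastasis-producing subpopulation.  Each shed
metastasis is viable with probability `q` (thinning) and waits
`Exponential(mean ρ)` before starting irreversible growth ("inception").
Secondary metastasis (metastasis-of-metastasis) is neglected.

**Metastasis growth and detection.**  From inception a metastasis grows at
rate `γ₀` until age `V` and `γ₁` afterwards; it is detectable at the survey
age `W` if its size reaches `m/c` cells (`m = 0.5 cm³`, `c = 10⁻⁹ cm³`).

**Size density.**  Conditional on their number, detectable sizes at `W`
are i.i.d. (as order statistics) with density
`p(x) ∝ λ(W−T−ψ(x))·ψ′(x)` on `[m, M]`, where `λ` is the inception
intensity (shedding convolved with latency) and `ψ` inverts the growth law.
Under the exponential laws this has closed forms in the parameters
`{A, M, a₀, a₁, b₀, b₁}` (see README), with a jump at `A` of size
`p(A+)/p(A−) = b₀/b₁ = γ₁/γ₀`, and is free of `α`, `q`, `n`; consequently
those three are not estimable from one size survey, and all "expected
count" outputs default to the relative scale `qα = 1`.

Four variants: `surgery` (resected, non-recurrent; no `a₁`),
`full` (primary in situ or recurrent; post-treatment shedding included),
and their homogeneous (`θ = 0 ⇒ a₀ = a₁ = 0`) special cases.  The variants
nest: `full → surgery` as `a₁ → −∞`, non-homogeneous → homogeneous as
`a₀ (, a₁) → 0`.

### Conventions adopted where the printed formulas conflict

These resolutions were fixed by re-deriving the density from the process
description; the first-principles quadrature density
(`theorem1_pdf_numeric`) agrees with the closed forms to ~1e-15 under them.

* The jump ratio is `p(A+)/p(A−) = b₀/b₁ = γ₁/γ₀` (the prose statement
  with the reciprocal ratio is a typo; the figure-caption value 3.5 for the
  first cohort patient matches `b₀/b₁`).
* The shedding integral's upper limit is `min{t, V−T}` only when the
  primary is actually gone; for an intact primary shedding continues over
  the full trajectory (this is what the full-model closed forms integrate).
  A `shedding_cap="fd10"` switch reproduces the printed truncated
  convention for comparison.
* In the expected-count formulas the latency cdf argument is `F(t−T−s)`
  (a function of the evaluation age), with an `fd12_verbatim` switch for
  the printed `F(W−T−s)`; the resected-primary cap is `min{t−T, V−T}`
  (times are measured from onset).

## Parameters

| symbol | meaning | units | notes |
|---|---|---|---|
| `β₀, β₁` | primary growth rates pre/post treatment | 1/yr | `β₁ = −∞`: resected |
| `γ₀, γ₁` | metastasis growth rates pre/post treatment | 1/yr | jump ratio `γ₁/γ₀` |
| `ρ` | mean metastasis latency | yr | exponential latency |
| `θ` | shedding exponent | — | `θ = 0`: homogeneous shedding |
| `α, q` | shedding scale, viability probability | 1/yr, — | only counts, never shape |
| `m, c` | detection threshold, cell volume | cm³ | 0.5 and 1e-9 |
| `A, M` | breakpoint and maximal size | cells | `1 < A < M`; support `[m, M]` |

Feasibility: `1 < A < M`, `A > m`, and `b₀/b₁ < V·ln A/((W−V)·ln(M/A))`
(equivalent to `T > 0`); `check_constraints` reports each.

## Numerics

* All densities and normalizers are evaluated in log space (sizes are cell
  counts, `ln M ≈ 25`); powers are `exp(k·ln ratio)`.
* Terms of the form `(u^z − 1)/z` go through `expm1`, which is exact for
  any `z ≠ 0`; only `z = 0` takes the analytic limit.  The full-model
  normalizer needs `(g(a₁,L) − g(−b₁,L))/(a₁+b₁)`, which cancels as
  `a₁ → −b₁`; for `|a₁+b₁| < 10⁻⁶·max(1,b₁)` a first/second-order series in
  the derivative of `g` is used.  The optimizer can therefore cross
  `a₀ = 0`, `a₁ + b₁ = 0` etc. without overflow.
* CDFs are closed-form branch integrals of the same guarded primitives
  (verified against adaptive quadrature to ~1e-12), so KS tests on
  thousands of points are exact and fast.
* The numerical oracle integrates the shedding/latency convolution with
  `scipy.integrate.quad` (absolute tolerance 1e-12), splitting at the
  treatment age; the density normalizer is computed in inception time (one
  nesting level less than integrating over sizes).
* Degenerate input `A ≤ m` selects the single-branch density; observations
  outside `[m, M]` make the likelihood `−∞` (reported as an infeasible
  flag, not an exception); at exactly `x = A` the upper branch applies.

## Fitting

The likelihood `L = n!·∏ p(Xᵢ)` is discontinuous in `A` at every observed
volume and multimodal, so the fit is staged: (1) differential evolution
(scipy, seeded, latin-hypercube init) over a log-parameter box —
`ln(A/m), ln(M/A)` spans up to `ln(50·x_max/m)`, `ln a₀, ln b₀, ln b₁ ∈
[−12, 6]`, `a₁ ∈ [−30, 5]` — with the onset-positivity constraint and
`M ≥ x_max` as smooth penalties; (2) a profile pass snapping `A` to the
right limit (`x·(1+10⁻⁹)`) of observed volumes at quantile positions, with
a reduced-dimension DE per snap; (3) Nelder–Mead polish of the leading
candidates and an iterative sweep of all observed volumes as breakpoints.
Nested fits are warm-started from their special case, so the richer variant
never scores worse.  Defaults (popsize 15, 250 generations, 2 restarts,
12 snap candidates) keep one 300-observation fit at ~3 s on one CPU while
reliably beating the generating parameters' likelihood in simulation; all
randomness derives from a single integer seed and refits are bit-identical.
`a₁`'s upper bound is positive (+5) so that the sign of the fitted `β₁` is
a genuine outcome — fitting the two-rate model to surgery data is the
model's self-consistency check and must be free to choose `β₁ > 0`.

The reported `−(log L)/n` excludes the `ln n!` term (the tabled
convention); the total log-likelihood including it is also reported.  The
maximizing parameters are independent of the cell volume `c` (only
`x·p(x)`, a function of size ratios, enters).

## Synthetic-data generator

`simulate_patient` draws shedding times by exact thinning of the piecewise
exponential intensity (17 sub-segments per growth phase keep the bound
tight), thins by viability, adds exponential latencies, grows each incepted
metastasis to the survey age and keeps volumes `≥ m`.  Three independent
seed-derived substreams (shedding / viability / latency) make the shedding
times invariant to `q`.  `α` is calibrated by the closed-form expected
detectable count, which is linear in `α`.

The generator and the closed-form densities share no code beyond the growth
law, so the KS cross-validation (pooled simulated volumes vs. closed-form
CDF, per variant) is a genuine two-implementation check.  What the
generator does **not** emulate: voxel-level measurement error (a 0.065 cm³
rounding switch exists but is off by default), non-exponential growth or
latency, multiple secondary sites, and secondary metastasis.  Passing
recovery tests therefore demonstrate internal consistency of
model + estimator, not robustness to real-data misspecification.

## Parameter recovery and its information limit

Recovery experiments simulate cohorts of ~300 detectable metastases and
refit.  `γ₁ = ln A/(W−V)` is recovered almost exactly (median error
< 0.1%): `A` is pinned by the data cluster at the breakpoint.  The
acceleration ratio `γ₁/γ₀ = b₀/b₁` is another matter: `b₁` is identified
*only* by observations below `A`.  For the first cohort patient's
reconstructed parameters, `P(X < A) = 0.030`, i.e. ~9 of 300 points.  An
idealized estimator that knows `A`, `m`, `b₀` and the normalization exactly
and estimates only `b₁` from Poisson(8.9) truncated-exponential draws
already has median relative error ≈ 27% (2000-replicate experiment); the
full five-parameter fit measures ≈ 35% (homogeneous) to ≈ 69% (with `a₀`
free, whose trade-off against `b₀` inflates the spread).  A 25% median
target at those study conditions is therefore unattainable for any
estimator, and the corresponding acceptance assertion documents this
expected failure rather than relaxing it.  Property tests of the estimator
use instead a truth chosen a priori in the informative regime (breakpoint
at 6 cm³, `b₀/b₁ = 2`, ~29% of mass below `A`), where the ratio is
recovered within 25% median.

The companion self-consistency experiment — fitting the two-primary-rate
model to synthetic resected-primary cohorts — returns large negative `β₁`
in every pilot seed, as it should: the data contain no post-treatment
shedding signal.

## Printed-value reproduction

The embedded cohort tables store every cell as its printed string.
Comparisons accept the looser of 2% relative error or half a unit in the
last printed digit (some rates are printed to one significant figure, e.g.
"0.5"); the onset age `T` is compared at 0.2 yr absolute because it is the
difference of two numbers of order `V` and inherits their rounding
amplified ~20-fold.  Reference patients 1, 2, 5, 11 are gated; patients
with `W−V` printed to 0.1 yr at magnitude ≤ 1.5 yr, or `b₁` printed to one
or two significant figures (3, 4, 6, 7, 10, 12), are reported with flags
only.  Two printed columns are not reproducible from printed inputs and
are never gated: the per-patient `−(log L)/n` values (they require the
unpublished volume lists) and the `β₁` column for the systemic-treatment
patients, which is numerically inconsistent with `β₁ = (a₁/a₀)·γ₁·ln S /
ln(M/A)` applied to the printed `a₀, a₁` (e.g. patient 8: −525 vs. printed
−30.7, while patient 6's printed −1.7/yr matches the separately printed
149-day primary shrinkage half-life, suggesting the column came from
unrounded fits or a separate calculation).

## Problem sizes

Tests run on one CPU in ~3 minutes: conversion and density checks are
instantaneous; oracle comparisons use 5 parameter sets × 17 grid points per
variant; KS cross-validations pool ~6000 simulated volumes per variant;
recovery experiments use 20 seeds × 300 observations (acceptance) and 6
seeds (property tests).  The acceptance script is pure desk arithmetic and
runs in seconds.

## Limitations

* Exponential growth throughout; the general growth-law machinery exists
  only in the numerical oracle, not as a fitting surface.
* No uncertainty quantification for the MLE (no standard errors or
  intervals); the recovery experiments are the honest substitute.
* `α` and `q` are not identifiable from a single size survey; all count
  outputs are relative unless the caller supplies them.
* Ages enter at full float precision; printed-table comparisons inherit
  the tables' 0.1-yr age rounding, which dominates the residual deviations.
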