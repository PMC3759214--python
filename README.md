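# metahist

Reconstruction of the individual natural history of metastatic cancer from a
single survey of metastasis sizes.

## The problem

A patient presents with a primary tumor (volume `S_v` at age `V`, when
treatment starts) and, at a later age `W`, a PET/CT survey shows `n`
detectable bone metastases with volumes `X_1 < … < X_n`.  Everything else —
when the disease started, when metastases were shed and seeded, how long
they lay dormant, how fast they grew before and after treatment — is
unobservable.  `metahist` implements a mechanistic stochastic model that
makes those quantities estimable from the size survey alone, for
biostatisticians and modelers studying metastatic progression and treatment
effects (the motivating application is prostate cancer, but the model is
generic to metastatic solid tumors).

## The model

* The primary grows exponentially: rate `β₀` from the onset age `T`
  (size 1 cell), rate `β₁` after treatment starts (`β₁ → −∞` encodes a
  non-recurrent resected primary).
* Metastases are shed by a Poisson process with intensity `α·Φ(t)^θ`, where
  `Φ(t)` is the primary size; each shed metastasis is viable with
  probability `q`, waits an exponential latency with mean `ρ`, then grows
  exponentially at rate `γ₀` before the start of treatment and `γ₁` after.
* A metastasis is detectable when its volume reaches `m = 0.5 cm³`
  (cell volume `c = 10⁻⁹ cm³`).

Conditional on their number, the detectable sizes at age `W` are
order statistics of an i.i.d. sample from a closed-form density `p(x)` on
`[m, M]` with parameters

    A = exp{γ₁(W−V)},  M = exp{γ₀(V−T) + γ₁(W−V)},
    a₀ = β₀θ/γ₀,  a₁ = β₁θ/γ₁,  b₀ = 1/(γ₀ρ),  b₁ = 1/(γ₁ρ),

free of `α`, `q` and `n`.  `A` — the size of a metastasis incepted exactly
at the start of treatment — is a jump point of the density with
`p(A+)/p(A−) = b₀/b₁ = γ₁/γ₀`: the size survey therefore carries a visible
signature of treatment-induced growth acceleration.  Four parametric
variants are implemented (surgery / intact primary, each with the
homogeneous `θ = 0` special case), with maximum likelihood estimation by
differential evolution + breakpoint snapping over `L = n!·∏p(Xᵢ)`, and a
forward simulator for validation and power studies.

## Worked example

`examples/01_reproduce_biological_parameters.py` converts the embedded
published fit of the first cohort patient (radical prostatectomy +
radiation; `A = 1.85 cm³`, `M = 29.74 cm³`, `a₀ = 3.62×10⁻⁴`, `b₀ = 12.00`,
`b₁ = 3.41`, ages 57.9/63.7, primary 27 cm³) into biological parameters:

```
patient 1 (radical prostatectomy + radiation):
  pre-treatment metastasis growth rate  gamma0 = 1.045 /yr
  post-treatment metastasis growth rate gamma1 = 3.679 /yr
  treatment-induced acceleration  gamma1/gamma0 = 3.52
  mean metastasis latency                  rho = 0.080 yr
  primary growth rate pre-treatment      beta0 = 9.04 /yr
  shedding exponent                      theta = 4.19e-05
  age at disease onset                       T = 55.2 yr
```

Read: the disease started ~2.7 years before treatment; metastases grew 3.5×
faster once the primary was removed; the shedding exponent is essentially
zero, i.e. the shedding rate did not depend on primary size (the
cancer-stem-cell signature).  For two systemic-treatment patients the same
conversion gives accelerations of 35.2× and 503.5×.

`examples/03_simulate_and_fit.py` closes the loop — simulate a synthetic
patient from a known truth and re-fit:

```
simulated 160 shed metastases, 155 detectable at survey (threshold 0.5 cm^3)
fit: -(logL)/n = 23.8893 over n = 155 volumes
                         true      fitted
gamma1 (/yr)           11.258     11.181
gamma1/gamma0           2.000      2.939
rho (yr)                0.089      0.092
onset age T (yr)        59.71      59.53
```

`examples/02_size_density.py` shows the density itself (and its agreement
with a first-principles numerical construction to ~1e-15), and
`examples/04_treatment_effect_summaries.py` the derived shedding-rate and
burden summaries.  A thin CLI wraps the same functions:
`metahist fit|simulate|convert|summarize|reproduce-table3`.

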