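# Methods

## The model

Cases are patients with at least *x* instances of one diagnostic code;
patients with an ambiguous count (0 < count < *x*) are dropped, and the
control pool of *m* individuals is fixed. Two phenomenological decay laws
describe what tightening the threshold does to the case group:

- **Misclassification decay.** The fraction of threshold-defined cases that
  are not true cases is *f(x)* = (1 − δ)ˣ, with 0 < δ < 1 per code. Each
  additional required instance removes the same proportion of remaining
  false positives; *f(0)* = 1 by construction (a zero-instance "definition"
  selects population draws). Equivalently PPV(*x*) = 1 − (1 − δ)ˣ.
- **Case attrition.** The expected case count is *nₓ* = *n₁* (1 + ε)⁻ˣ with
  ε ≥ 0, anchored at the one-instance count *n₁*. The curve is taken
  literally, so the value it assigns at *x* = 1 is *n₁*/(1 + ε); *n₁* is the
  anchor of the decay law, not the count it returns at *x* = 1. Expected
  counts are kept real-valued internally; rounding to whole persons happens
  only when simulating.

Genetics enter through the population risk-allele frequency *q* (assumed to
hold in controls) and the allelic relative risk *R*. True cases carry the
allele at frequency *p* = *Rq* / (1 + (*R* − 1)*q*); the threshold-defined
case group is a mixture, *s* = *f q* + (1 − *f*) *p*.

Power for the allele-count two-proportion test is approximated by
Φ(√λ − z₁₋α/₂) with λ = *N*(*q* − *s*)² / [*q*(1 − *q*) + *s*(1 − *s*)] and
*N* = 4 *nₓ m* / (*nₓ* + *m*) (twice the harmonic mean of the group sizes,
in alleles). This is a one-tail approximation to the two-sided test: mass
in the wrong tail is ignored, so power at λ = 0 is α/2, not α.

## Parameters

| name | meaning | range | default |
|---|---|---|---|
| `q` | population risk-allele frequency | (0, 1) | — |
| `R` | allelic relative risk | > 0 | — |
| `n1` | expected cases at the one-instance definition | > 0 | — |
| `m` | control count | > 0 | — |
| `delta` | misclassification decay per instance | (0, 1) | — |
| `epsilon` | case-attrition rate per instance | ≥ 0 | — |
| `alpha` | two-sided significance level | (0, 1) | 0.05 |

α is defaulted rather than required because the optimal threshold is
provably independent of it: power is a strictly increasing transform of λ,
so α only rescales reported power values. Frequencies are validated to the
open interval (0, 1); boundary inputs are rejected, not clamped.

## Optimization

The optimal continuous threshold maximizes λ(*x*). Rather than transcribing
an expanded closed-form stationarity polynomial, the residual is derived by
the chain rule on ln λ = ln *N* + ln *g*, *g* = (*q* − *s*)²/[*q*(1 − *q*) +
*s*(1 − *s*)]:

    d ln N / dx = −ln(1+ε) · m / (nₓ + m)
    s′          = ln(1−δ) · f(x) · (q − p)
    d ln g / dx = s′ · [ 2/(s − q) − (1 − 2s) / (q(1−q) + s(1−s)) ]

The residual is verified in the test suite against central finite
differences (step 10⁻⁶) over randomized admissible parameters.

Numerics: bounded Brent maximization of ln λ over a configurable bracket
(default [0.5, 50] instances — no plausible design requires more than 50
code instances), internal tolerance 10⁻⁸, followed by a Brent root solve of
the analytic residual when the maximizer is interior. A maximizer within
tolerance of a bracket endpoint sets `boundary_flag` instead of raising, so
sweeps may include monotone cases such as ε = 0 (no attrition: λ increases
without bound in *x* when *m* ≫ *nₓ*). The null variant *R* = 1 makes λ ≡ 0
and raises `DegenerateModelError`. The integer recommendation is the
exhaustive argmax of λ over 1..x_max; ties within 10⁻¹² break toward
smaller *x*, which retains more cases.

## Simulation

`empirical_power` draws case allele counts Binomial(2·round(*nₓ*), *s*) and
control counts Binomial(2*m*, *q*) and applies the pooled-variance
two-proportion z-test — the same asymptotic family as the analytic formula,
so the comparison isolates the quality of the normal approximation rather
than mixing in exact-test discreteness. The test statistic is vectorized in
numpy; the unit suite cross-checks its p-values against statsmodels'
`proportions_ztest` to 10⁻¹⁰.

The approximation is good but not exact: the closed form uses the
equal-weighted variance (*q*(1−*q*) + *s*(1−*s*))/*N*, whereas the pooled
test's null variance is driven by the control frequency when *m* ≫ *nₓ*.
Under the reference design the resulting bias grows toward the sparse end
of the curve (expected cases ≈ 49 at *x* = 15) and can reach ≈ 0.02 in
absolute power — larger than three Monte Carlo standard errors at 10,000
replicates. The suite therefore checks the simulation two ways: a strict
3-SE agreement test at five design thresholds (which documents exactly
where the approximation's bias exceeds Monte Carlo resolution) and an
approximation-quality bound of 0.03 absolute that holds across the design
range. Null calibration (R = 1 rejection rate ≈ α) is checked at α = 0.05
and 0.01.

`simulate_code_counts` builds per-patient records (instance count, latent
true-case status) by inverting the two decay laws: the count distribution
is the first difference of the geometric survival tail, and the true-case
probability at each count level is the ratio of the differenced joint tail
*nₓ*(1 − *f(x)*) to the differenced survival tail. This is the minimal
construction reproducing both threshold curves exactly in expectation —
**when it exists**. A fixed per-patient labeling requires the expected
number of *true* cases to shrink (weakly) as the threshold tightens, i.e.
ε ≥ 1 − δ. Outside that regime (including δ = ε = 0.15) the two laws
jointly imply more true cases at stricter thresholds, which no single
labeling can realize: the two decay laws are separate empirical fits, not a
coherent joint patient-level law. The generator raises
`InfeasibleModelError` naming the offending level rather than silently
clipping. Levels with zero occupancy (ε = 0 puts all patients at the cap)
are exempt from the check, since no mass is realizable there.

`simulate_calibration_tables` sidesteps the joint-labeling constraint by
simulating what is actually observed in practice: patient counts give the
threshold-count table, and the chart review at each threshold is an
independent Binomial draw with success probability PPV(*x*). Because
reviews are per-threshold, both curves are matched in expectation for any
admissible (δ, ε); this is the route used for end-to-end calibration
validation.

What the simulations do not emulate: longitudinal code timing, correlated
repeat encounters, control-group contamination, genotype-level (rather than
allele-level) sampling, and any dependence between a patient's code count
and their genotype beyond true-case status. Passing tests therefore
demonstrate internal consistency of the model and estimators, not fidelity
to any specific EHR system.

## Calibration

δ and ε are fitted by ordinary least squares on the log scale, where both
decay laws are linear — transparent, and exact on noiseless model data:

- ε: regress ln *nₓ* on *x* with intercept; ε̂ = exp(−slope) − 1 and
  n̂₁ = exp(intercept).
- δ: regress ln(1 − PPV(*x*)) on *x* **through the origin**, because
  *f(0)* = 1 is exact in the model; δ̂ = 1 − exp(slope). Saturated points
  (PPV = 1) have no finite log and are rejected with instructions to
  exclude them.

Weighted or likelihood-based estimators, confidence intervals beyond
residual diagnostics, and alternative decay families are deliberately out
of scope; the single-parameter geometric family is the model, and the fits
are meant to be auditable by hand.

## Problem sizes

Default study sizes used throughout the tests: 200,000 simulated patients
for moment-matching and calibration recovery (binomial error ≈ 0.002 on a
PPV near 0.68), 10,000 replicates for Monte Carlo power (SE ≤ 0.005), 200
randomized parameter draws for the derivative and grid-oracle checks, and a
dense grid of step 10⁻³ over [0.5, 50] for the brute-force argmax oracle.

## Known limitations

- The power formula's accuracy degrades for very small case groups
  (tens of cases): its variance weighting differs from the pooled test's,
  as quantified above. Optima are unaffected in the cases examined (the
  argmax of λ and of true power coincide at the reference design), but
  reported absolute power near the curve's sparse end can be off by ~0.02.
- Control allele frequency is fixed at *q*: control-group misclassification
  is not modeled.
- One code, one (δ, ε) pair per run; no joint optimization over multiple
  codes and no 2-D parameter grids.
- The geometric decay laws are convenient single-parameter summaries; real
  codes can deviate substantially, and the calibration fits' residuals are
  the place to check.
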