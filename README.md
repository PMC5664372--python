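# icdpower

Power and experimental-design optimization for genetic association studies
whose cases are defined from electronic health records by the "rule of N":
a patient is a case when their record carries at least *x* instances of a
diagnostic (ICD) code.

Raising the instance threshold *x* makes the case group purer but smaller.
`icdpower` quantifies that trade-off analytically, finds the threshold that
maximizes power, validates the approximation by Monte Carlo simulation, and
calibrates the per-code decay parameters from observed data. It is aimed at
statistical geneticists and EHR/biobank analysts planning PheWAS-style or
single-phenotype association scans on code-defined phenotypes.

## Model

For a biallelic marker with population risk-allele frequency *q* and
allelic relative risk *R* = P(A₂|case)/P(A₂|control):

- misclassification among threshold-defined cases decays geometrically,
  *f(x)* = (1 − δ)ˣ, so the positive predictive value of the definition is
  PPV(*x*) = 1 − (1 − δ)ˣ;
- the eligible case pool shrinks geometrically, *nₓ* = *n₁* (1 + ε)⁻ˣ,
  anchored at the expected case count *n₁* of the one-instance definition;
- the expected case allele frequency is the mixture
  *s* = *f q* + (1 − *f*) · *Rq* / (1 + (*R* − 1) *q*);
- with *m* controls and effective allele count *N* = 4 *nₓ m* / (*nₓ* + *m*),
  the two-proportion z-test has noncentrality
  λ = *N* (*q* − *s*)² / [*q*(1 − *q*) + *s*(1 − *s*)] and approximate power
  Φ(√λ − z₁₋α/₂).

The optimal threshold maximizes λ(*x*) (and hence power at every α); the
stationarity condition d ln λ/d*x* = 0 is solved numerically. δ and ε are
estimable per code by log-linear least squares from a threshold-count table
and a chart-review PPV table.

## Worked example

The reference design: 10,000 controls, 400 expected cases at the
one-instance definition, *R* = 2, *q* = 0.20, δ = ε = 0.15.

```sh
icdpower optimize --q 0.2 --R 2 --n1 400 --m 10000 --delta 0.15 --epsilon 0.15
```

prints

```json
{
  "x_continuous": 7.226491795,
  "x_integer": 7,
  "ncp_continuous": 13.29323084,
  "ncp_integer": 13.28174056,
  "power_integer": 0.9539524639,
  "alpha": 0.05,
  "boundary_flag": false,
  "seed": 0
}
```

Read: the continuous maximizer of λ(x) is x\* ≈ 7.23, so requiring **seven**
instances of the code is the best integer design; it keeps an expected 150
cases (down from 400) at 68% PPV and achieves ≈ 0.954 power at α = 0.05.
`boundary_flag: false` confirms the optimum is interior, not an artifact of
the search bracket.

The same is available from Python:

```python
from icdpower import GeneticArchitecture, CohortSpec, CodeAttrition, optimal_x_integer

rep = optimal_x_integer(
    GeneticArchitecture(q=0.20, R=2.0),
    CohortSpec(n1=400, m=10_000),
    CodeAttrition(delta=0.15, epsilon=0.15),
)
rep.x_integer   # 7
```

Other subcommands: `power` (one design point), `scan` (power-vs-x tables
and one-parameter sweeps as CSV), `simulate` (Monte Carlo power and
synthetic code-count samples), `calibrate` (fit δ and ε from
`x,n_x` / `x,ppv` CSV tables). See `icdpower --help`.

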