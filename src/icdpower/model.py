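"""Closed-form power model for ICD-code-defined case/control association scans.

Cases are patients with at least ``x`` instances of a diagnostic code. Raising
the threshold ``x`` makes the case group purer (the misclassified fraction
decays geometrically, ``f(x) = (1 - delta)**x``) but smaller (the eligible
case pool shrinks geometrically, ``n_x = n1 * (1 + epsilon)**-x``). Power for
the allele-count two-proportion z-test follows from the noncentrality

    lambda = N (q - s)^2 / [q(1-q) + s(1-s)],   N = 4 n_x m / (n_x + m),

where ``q`` is the population (control) frequency of the risk allele and
``s`` the expected frequency among threshold-defined cases, a mixture of the
true-case frequency ``Rq / (1 + (R-1)q)`` and ``q`` weighted by ``1 - f`` and
``f``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = [
    "GeneticArchitecture",
    "CohortSpec",
    "CodeAttrition",
    "DesignQuery",
    "PowerPoint",
    "misclassification_fraction",
    "case_count",
    "case_allele_frequency",
    "effective_allele_sample",
    "noncentrality",
    "power",
    "evaluate_design",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class GeneticArchitecture:
    """Risk variant: population minor-allele frequency and allelic relative risk.

    Parameters
    ----------
    q : float
        Frequency of the risk allele A2 in the general population (and,
        by assumption, in controls); must lie strictly in (0, 1).
    R : float
        Allelic relative risk, ``R = P(A2 | case) / P(A2 | control)``;
        must be positive. ``R = 1`` is the null variant.
    """

    q: float
    R: float

    def __post_init__(self) -> None:
        _require(0.0 < self.q < 1.0, f"q must be in (0, 1), got {self.q}")
        _require(self.R > 0.0, f"R must be > 0, got {self.R}")

    @property
    def true_case_frequency(self) -> float:
        """Expected A2 frequency among true cases, ``Rq / (1 + (R-1)q)``."""
        return self.R * self.q / (1.0 + (self.R - 1.0) * self.q)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort sizes: expected cases at the one-instance definition and controls.

    ``n1`` is the expected case count when a single code instance defines a
    case; it anchors the attrition curve and may be non-integer. ``m`` is the
    fixed control count, typically much larger than the case pool.
    """

    n1: float
    m: float

    def __post_init__(self) -> None:
        _require(self.n1 > 0.0, f"n1 must be > 0, got {self.n1}")
        _require(self.m > 0.0, f"m must be > 0, got {self.m}")


@dataclass(frozen=True)
class CodeAttrition:
    """Per-code decay parameters of an ICD code.

    ``delta`` governs how fast misclassification falls with each additional
    code instance (``f(x) = (1 - delta)**x``); ``epsilon`` governs how fast
    the case pool shrinks (``n_x = n1 (1 + epsilon)**-x``). Both are
    estimable per code from threshold-count and chart-review tables (see
    :mod:`icdpower.calibration`).
    """

    delta: float
    epsilon: float

    def __post_init__(self) -> None:
        _require(0.0 < self.delta < 1.0, f"delta must be in (0, 1), got {self.delta}")
        _require(self.epsilon >= 0.0, f"epsilon must be >= 0, got {self.epsilon}")


@dataclass(frozen=True)
class DesignQuery:
    """One design to evaluate: instance threshold ``x`` and significance level."""

    x: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        _require(self.x >= 0.0, f"x must be >= 0, got {self.x}")
        _require(0.0 < self.alpha < 1.0, f"alpha must be in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class PowerPoint:
    """A fully evaluated design point.

    Attributes
    ----------
    x : float
        Instance threshold.
    n_x : float
        Expected case count at this threshold.
    f : float
        Misclassification fraction among threshold-defined cases.
    s : float
        Expected risk-allele frequency in cases.
    N : float
        Effective allele sample size, ``4 n_x m / (n_x + m)``.
    ncp : float
        Noncentrality parameter lambda.
    power : float
        Approximate power ``Phi(sqrt(lambda) - z_{1-alpha/2})``.
    alpha : float
        Two-sided significance level used for ``power``.
    """

    x: float
    n_x: float
    f: float
    s: float
    N: float
    ncp: float
    power: float
    alpha: float


def misclassification_fraction(attrition: CodeAttrition, x: float) -> float:
    """Expected fraction of threshold-defined cases that are not true cases.

    Geometric decay ``f(x) = (1 - delta)**x``: each additional required code
    instance removes the same proportion of the remaining false positives.
    ``1 - f(x)`` is the positive predictive value of the case definition.
    """
    _require(x >= 0.0, f"x must be >= 0, got {x}")
    return (1.0 - attrition.delta) ** x


def case_count(cohort: CohortSpec, attrition: CodeAttrition, x: float) -> float:
    """Expected case count at threshold ``x``: ``n1 * (1 + epsilon)**-x``.

    The curve is anchored so that ``x = 0`` returns ``n1``; with
    ``epsilon = 0`` the pool does not shrink.
    """
    _require(x >= 0.0, f"x must be >= 0, got {x}")
    return cohort.n1 * (1.0 + attrition.epsilon) ** (-x)


def case_allele_frequency(gen: GeneticArchitecture, f: float) -> float:
    """Expected risk-allele frequency in the mixed case group.

    A fraction ``f`` of threshold-defined cases are population draws
    (frequency ``q``); the remainder are true cases (frequency
    ``Rq / (1 + (R-1)q)``, by Bayes' theorem from the allelic relative risk).
    """
    _require(0.0 <= f <= 1.0, f"f must be in [0, 1], got {f}")
    return f * gen.q + (1.0 - f) * gen.true_case_frequency


def effective_allele_sample(n_x: float, m: float) -> float:
    """Effective allele count ``N = 4 n_x m / (n_x + m)``.

    Twice the harmonic mean of the two group sizes, in alleles: the sample
    size at which a balanced design would match the variance of the observed
    unbalanced one. Symmetric in its arguments; tends to ``4 n_x`` as
    ``m -> inf``.
    """
    _require(n_x > 0.0, f"n_x must be > 0, got {n_x}")
    _require(m > 0.0, f"m must be > 0, got {m}")
    return 4.0 * n_x * m / (n_x + m)


def noncentrality(q: float, s: float, N: float) -> float:
    """Noncentrality ``lambda = N (q - s)^2 / [q(1-q) + s(1-s)]``.

    Zero exactly when the case and control frequencies coincide; invariant
    under swapping ``q`` and ``s``. Frequencies must be strictly inside
    (0, 1) — a degenerate frequency makes the variance term meaningless.
    """
    _require(0.0 < q < 1.0, f"q must be in (0, 1), got {q}")
    _require(0.0 < s < 1.0, f"s must be in (0, 1), got {s}")
    _require(N > 0.0, f"N must be > 0, got {N}")
    return N * (q - s) ** 2 / (q * (1.0 - q) + s * (1.0 - s))


def power(ncp: float, alpha: float) -> float:
    """Approximate two-sided power ``Phi(sqrt(lambda) - z_{1-alpha/2})``.

    One-tail normal approximation to the two-sided two-proportion test on
    allele counts: the probability mass in the opposite tail is ignored, so
    ``power(0, alpha) = alpha / 2`` rather than ``alpha``.
    """
    _require(ncp >= 0.0, f"ncp must be >= 0, got {ncp}")
    _require(0.0 < alpha < 1.0, f"alpha must be in (0, 1), got {alpha}")
    return float(norm.cdf(math.sqrt(ncp) - norm.ppf(1.0 - alpha / 2.0)))


def evaluate_design(
    gen: GeneticArchitecture,
    cohort: CohortSpec,
    attrition: CodeAttrition,
    query: DesignQuery,
) -> PowerPoint:
    """Evaluate one design end to end and return the populated :class:`PowerPoint`."""
    f = misclassification_fraction(attrition, query.x)
    n_x = case_count(cohort, attrition, query.x)
    s = case_allele_frequency(gen, f)
    N = effective_allele_sample(n_x, cohort.m)
    ncp = noncentrality(gen.q, s, N)
    return PowerPoint(
        x=query.x,
        n_x=n_x,
        f=f,
        s=s,
        N=N,
        ncp=ncp,
        power=power(ncp, query.alpha),
        alpha=query.alpha,
    )
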