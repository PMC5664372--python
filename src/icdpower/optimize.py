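"""Optimal instance threshold: solve the stationarity condition for lambda(x).

The noncentrality lambda(x) trades case purity against case count. Its
interior maximum satisfies d ln lambda / dx = 0, obtained by the chain rule:

    d ln N / dx = -ln(1+eps) * m / (n_x + m)
    d ln g / dx = s' * [ 2/(s - q) - (1 - 2s) / (q(1-q) + s(1-s)) ]
    s'          = ln(1-delta) * f(x) * (q - p),   p = Rq / (1 + (R-1)q)

with g the effect-size factor (q-s)^2 / [q(1-q)+s(1-s)]. The maximizer is
located by bounded scalar maximization of ln lambda; the analytic residual
refines and verifies the result. Because power is a strictly increasing
transform of lambda at any alpha, the optimal x does not depend on alpha.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

from scipy.optimize import brentq, minimize_scalar

from .model import (
    CodeAttrition,
    CohortSpec,
    DesignQuery,
    GeneticArchitecture,
    case_allele_frequency,
    case_count,
    evaluate_design,
    misclassification_fraction,
    power,
)

__all__ = [
    "OptimumReport",
    "DegenerateModelError",
    "ncp_of_x",
    "stationarity_residual",
    "optimal_x_continuous",
    "optimal_x_integer",
]

DEFAULT_BRACKET = (0.5, 50.0)
_XTOL = 1e-8  # internal optimizer tolerance; results quoted to 1e-6


class DegenerateModelError(ValueError):
    """The objective is identically zero (s = q for all x, e.g. R = 1)."""


@dataclass(frozen=True)
class OptimumReport:
    """Continuous and integer optimal thresholds with their objective values.

    ``boundary_flag`` marks a monotone objective over the search bracket:
    the continuous "optimum" then sits at a bracket endpoint and the integer
    constraint on ``x_integer in {floor, ceil}`` of it is not enforced.
    """

    x_continuous: float
    x_integer: int
    ncp_continuous: float
    ncp_integer: float
    power_integer: float
    alpha: float
    boundary_flag: bool

    def to_dict(self) -> dict:
        return asdict(self)


def ncp_of_x(
    gen: GeneticArchitecture,
    cohort: CohortSpec,
    attrition: CodeAttrition,
    x: float,
) -> float:
    """Noncentrality lambda as a smooth function of the (real) threshold x."""
    return evaluate_design(gen, cohort, attrition, DesignQuery(x=x)).ncp


def stationarity_residual(
    gen: GeneticArchitecture,
    cohort: CohortSpec,
    attrition: CodeAttrition,
    x: float,
) -> float:
    """d ln lambda / dx at x; zero exactly at interior optima of lambda.

    Raises
    ------
    DegenerateModelError
        If the model admits no frequency difference (``R = 1``), where
        ln lambda is undefined.
    """
    if x <= 0.0:
        raise ValueError(f"x must be > 0, got {x}")
    q = gen.q
    p = gen.true_case_frequency
    if p == q:
        raise DegenerateModelError("s = q for all x (null variant R = 1)")
    f = misclassification_fraction(attrition, x)
    n_x = case_count(cohort, attrition, x)
    s = case_allele_frequency(gen, f)
    if s == q:  # delta -> 0 keeps f = 1 forever
        raise DegenerateModelError("s = q at this x (no misclassification decay)")
    s_prime = math.log(1.0 - attrition.delta) * f * (q - p)
    denom = q * (1.0 - q) + s * (1.0 - s)
    d_ln_N = -math.log(1.0 + attrition.epsilon) * cohort.m / (n_x + cohort.m)
    d_ln_g = s_prime * (2.0 / (s - q) - (1.0 - 2.0 * s) / denom)
    return d_ln_N + d_ln_g


def optimal_x_continuous(
    gen: GeneticArchitecture,
    cohort: CohortSpec,
    attrition: CodeAttrition,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
) -> tuple[float, bool]:
    """Maximize lambda(x) over the bracket; return (x*, boundary_flag).

    Bounded Brent maximization of ln lambda, refined by a Brent root solve of
    the analytic stationarity residual when the maximizer is interior. The
    flag is set when the objective is monotone over the bracket (maximizer
    within tolerance of an endpoint), e.g. for ``epsilon = 0``.
    """
    lo, hi = bracket
    if not (lo >= 0.0 and hi > lo):
        raise ValueError(f"invalid bracket {bracket}")
    if gen.R == 1.0:
        raise DegenerateModelError("lambda(x) is identically zero for R = 1")

    res = minimize_scalar(
        lambda x: -math.log(ncp_of_x(gen, cohort, attrition, x)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": _XTOL},
    )
    x_star = float(res.x)
    edge_tol = 10.0 * _XTOL + 1e-4 * (hi - lo)
    at_boundary = x_star - lo < edge_tol or hi - x_star < edge_tol
    if at_boundary:
        # monotone objective: report the better endpoint exactly
        x_star = lo if ncp_of_x(gen, cohort, attrition, max(lo, 1e-12)) >= ncp_of_x(
            gen, cohort, attrition, hi
        ) else hi
        return x_star, True

    # refine with the analytic residual (sign change straddles the optimum)
    h = max(1e-3, 10 * _XTOL)
    a, b = max(lo, x_star - h), min(hi, x_star + h)
    ra = stationarity_residual(gen, cohort, attrition, a)
    rb = stationarity_residual(gen, cohort, attrition, b)
    if ra > 0.0 > rb:
        x_star = brentq(
            lambda x: stationarity_residual(gen, cohort, attrition, x),
            a,
            b,
            xtol=1e-12,
        )
    return float(x_star), False


def optimal_x_integer(
    gen: GeneticArchitecture,
    cohort: CohortSpec,
    attrition: CodeAttrition,
    x_max: int = 50,
    alpha: float = 0.05,
    bracket: tuple[float, float] | None = None,
) -> OptimumReport:
    """Best integer threshold in 1..x_max, with the continuous solution attached.

    The integer argmax is found by exhaustive enumeration of lambda (ties,
    within 1e-12, broken toward smaller x, which retains more cases). The
    optimum is independent of alpha; alpha only scales the reported power.
    """
    if x_max < 1:
        raise ValueError(f"x_max must be >= 1, got {x_max}")
    if bracket is None:
        bracket = (DEFAULT_BRACKET[0], max(DEFAULT_BRACKET[1], float(x_max)))
    x_cont, boundary = optimal_x_continuous(gen, cohort, attrition, bracket)

    best_x, best_ncp = 1, -math.inf
    for k in range(1, x_max + 1):
        ncp_k = ncp_of_x(gen, cohort, attrition, float(k))
        if ncp_k > best_ncp + 1e-12:
            best_x, best_ncp = k, ncp_k
    return OptimumReport(
        x_continuous=x_cont,
        x_integer=best_x,
        ncp_continuous=ncp_of_x(gen, cohort, attrition, x_cont),
        ncp_integer=best_ncp,
        power_integer=power(best_ncp, alpha),
        alpha=alpha,
        boundary_flag=boundary,
    )
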