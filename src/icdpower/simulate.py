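"""Monte Carlo machinery: synthetic code-count data and empirical power.

Two generators, both seeded and fully reproducible:

* per-patient code counts with latent true-case status, constructed so that
  the expected survival curve ``#{count >= x}`` and the expected positive
  predictive value ``PPV(x) = 1 - (1 - delta)**x`` both match the analytic
  decay model exactly (the level distribution is the first difference of the
  geometric tail; true-case status the first difference of the joint tail);
* case/control allele counts under the mixture case frequency, tested with
  the pooled two-proportion z-test — the same normal approximation whose
  power formula the simulation validates.

A single fixed truth labeling can reproduce both decay curves only when
``epsilon >= 1 - delta``: otherwise the implied number of *true* cases grows
as the threshold tightens, which no per-patient labeling can realize (the
two decay laws are separate empirical fits, not a joint patient-level law).
:func:`simulate_code_counts` raises :class:`InfeasibleModelError` in that
regime; :func:`simulate_calibration_tables` sidesteps it by simulating each
threshold's chart review independently, and works for all parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import (
    CodeAttrition,
    CohortSpec,
    DesignQuery,
    GeneticArchitecture,
    evaluate_design,
)

__all__ = [
    "CodeCountSample",
    "AssociationReplicate",
    "EmpiricalPower",
    "InfeasibleModelError",
    "simulate_code_counts",
    "simulate_calibration_tables",
    "simulate_association",
    "empirical_power",
    "two_proportion_z_pvalue",
]


class InfeasibleModelError(ValueError):
    """Parameters imply a per-level true-case probability outside [0, 1]."""


@dataclass(frozen=True)
class CodeCountSample:
    """Per-patient (instance_count, is_true_case) records plus the seed used."""

    records: pd.DataFrame
    seed: int

    def survival_counts(self, x_max: int) -> np.ndarray:
        """Number of patients with at least x instances, for x = 1..x_max."""
        counts = self.records["instance_count"].to_numpy()
        return np.array([(counts >= x).sum() for x in range(1, x_max + 1)])

    def empirical_ppv(self, x: int) -> float:
        """Share of true cases among patients with at least ``x`` instances."""
        sel = self.records["instance_count"] >= x
        if not sel.any():
            raise ValueError(f"no patients with count >= {x}")
        return float(self.records.loc[sel, "is_true_case"].mean())

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


@dataclass(frozen=True)
class AssociationReplicate:
    """One simulated case/control allele-count comparison with its p-value."""

    case_allele_count: int
    control_allele_count: int
    case_n_alleles: int
    control_n_alleles: int
    p_value: float


@dataclass(frozen=True)
class EmpiricalPower:
    """Monte Carlo power estimate with its binomial standard error."""

    estimate: float
    std_error: float
    n_reps: int
    analytic: float
    seed: int


def _level_distribution(
    attrition: CodeAttrition, x_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """Level masses and per-level true-case probabilities for levels 1..x_max.

    Tail of the level distribution (conditioned on >= 1 instance) is
    ``(1+eps)**-(x-1)``; the joint true-case tail is that times
    ``1 - (1-delta)**x``. First differences give the per-level masses; the
    last level absorbs the full remaining tail.
    """
    x = np.arange(1, x_max + 2, dtype=float)
    tail = (1.0 + attrition.epsilon) ** (-(x - 1.0))
    joint = tail * (1.0 - (1.0 - attrition.delta) ** x)
    p_level = tail[:-1] - tail[1:]
    p_joint = joint[:-1] - joint[1:]
    # last level keeps its whole tail
    p_level[-1] = tail[-2]
    p_joint[-1] = joint[-2]
    for i, (pl, pj) in enumerate(zip(p_level, p_joint), start=1):
        if pl < -1e-15:
            raise InfeasibleModelError(f"level {i}: negative level mass {pl}")
        if pl <= 1e-12:
            continue  # unoccupied level (epsilon = 0): nothing to realize
        if not (-1e-15 <= pj <= pl + 1e-15):
            raise InfeasibleModelError(
                f"level {i}: true-case mass {pj} outside [0, {pl}]"
            )
    with np.errstate(invalid="ignore", divide="ignore"):
        p_true = np.where(p_level > 0.0, p_joint / np.where(p_level > 0, p_level, 1.0), 0.0)
    return np.clip(p_level, 0.0, None), np.clip(p_true, 0.0, 1.0)


def simulate_code_counts(
    cohort: CohortSpec,
    attrition: CodeAttrition,
    n_patients: int,
    x_max: int = 20,
    seed: int = 0,
) -> CodeCountSample:
    """Draw per-patient instance counts and latent true-case status.

    Every simulated patient has at least one instance of the code (patients
    with zero instances never enter a threshold-defined case group). With
    ``epsilon = 0`` the tail never decays, so every patient sits at
    ``x_max`` — the attrition-free limit.
    """
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    if x_max < 1:
        raise ValueError(f"x_max must be >= 1, got {x_max}")
    p_level, p_true = _level_distribution(attrition, x_max)
    rng = np.random.default_rng(seed)
    levels = rng.choice(np.arange(1, x_max + 1), size=n_patients, p=p_level / p_level.sum())
    truth = rng.random(n_patients) < p_true[levels - 1]
    records = pd.DataFrame(
        {"instance_count": levels.astype(int), "is_true_case": truth.astype(int)}
    )
    return CodeCountSample(records=records, seed=seed)


def simulate_calibration_tables(
    cohort: CohortSpec,
    attrition: CodeAttrition,
    n_patients: int,
    x_range: tuple[int, int] = (1, 8),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the observed inputs of per-code calibration: count and PPV tables.

    Patient instance counts are drawn from the differenced geometric tail of
    the attrition curve; the count table records how many patients survive
    each threshold. The chart review at each threshold ``x`` is then
    simulated independently — the number of confirmed true cases among the
    surviving patients is Binomial with success probability
    ``1 - (1 - delta)**x`` — mirroring how PPV is measured in practice
    (a review of the threshold-defined case group). Because reviews are
    per-threshold, both decay curves are matched in expectation for *any*
    admissible (delta, epsilon), including regimes where no single truth
    labeling exists.

    Returns
    -------
    (counts, ppv) : tuple of DataFrame
        ``counts`` has columns ``x, n_x``; ``ppv`` has columns ``x, ppv``.
        Thresholds with no surviving patients are dropped.
    """
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    lo, hi = int(x_range[0]), int(x_range[1])
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid x_range {x_range}")
    rng = np.random.default_rng(seed)
    x_grid = np.arange(lo, hi + 1)
    # level distribution over 1..hi (+1 catch-all for counts beyond the grid)
    tail = (1.0 + attrition.epsilon) ** (-(np.arange(1, hi + 2, dtype=float) - 1.0))
    p_level = np.append(tail[:-1] - tail[1:], tail[-1])
    levels = rng.choice(np.arange(1, hi + 2), size=n_patients, p=p_level / p_level.sum())
    surviving = np.array([(levels >= x).sum() for x in x_grid])
    keep = surviving > 0
    x_kept = x_grid[keep]
    n_kept = surviving[keep]
    ppv_expected = 1.0 - (1.0 - attrition.delta) ** x_kept
    confirmed = rng.binomial(n_kept, ppv_expected)
    counts = pd.DataFrame({"x": x_kept, "n_x": n_kept})
    ppv = pd.DataFrame({"x": x_kept, "ppv": confirmed / n_kept})
    return counts, ppv


def two_proportion_z_pvalue(
    k1: np.ndarray, n1: int, k2: np.ndarray, n2: int
) -> np.ndarray:
    """Two-sided pooled-variance z-test p-values for success counts k1/n1 vs k2/n2.

    Vectorized over replicates. Degenerate pooled frequencies (all successes
    or all failures in both groups) give p = 1.
    """
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    pooled = (k1 + k2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0.0, (k1 / n1 - k2 / n2) / np.sqrt(var), 0.0)
    return 2.0 * norm.sf(np.abs(z))


def simulate_association(
    gen: GeneticArchitecture,
    s: float,
    n_cases: int,
    m: int,
    seed: int = 0,
) -> AssociationReplicate:
    """One replicate: binomial allele counts and the pooled z-test p-value.

    Case alleles ~ Binomial(2 n_cases, s); control alleles ~ Binomial(2m, q).
    """
    if not (0.0 < s < 1.0):
        raise ValueError(f"s must be in (0, 1), got {s}")
    if n_cases < 1 or m < 1:
        raise ValueError("n_cases and m must be >= 1")
    rng = np.random.default_rng(seed)
    na, nb = 2 * n_cases, 2 * m
    k1 = int(rng.binomial(na, s))
    k2 = int(rng.binomial(nb, gen.q))
    p = float(two_proportion_z_pvalue(np.array([k1]), na, np.array([k2]), nb)[0])
    return AssociationReplicate(
        case_allele_count=k1,
        control_allele_count=k2,
        case_n_alleles=na,
        control_n_alleles=nb,
        p_value=p,
    )


def empirical_power(
    gen: GeneticArchitecture,
    cohort: CohortSpec,
    attrition: CodeAttrition,
    query: DesignQuery,
    n_reps: int = 10_000,
    seed: int = 0,
) -> EmpiricalPower:
    """Monte Carlo power at one design point, with binomial standard error.

    The expected case count is rounded to the nearest whole person before
    sampling; the rejection rule is the two-sided pooled z-test at the
    query's alpha. The analytic approximation for the same design is
    attached for side-by-side comparison.
    """
    if n_reps < 100:
        raise ValueError(f"n_reps must be >= 100, got {n_reps}")
    pt = evaluate_design(gen, cohort, attrition, query)
    n_cases = max(1, round(pt.n_x))
    m = max(1, round(cohort.m))
    na, nb = 2 * n_cases, 2 * m
    rng = np.random.default_rng(seed)
    k1 = rng.binomial(na, pt.s, size=n_reps)
    k2 = rng.binomial(nb, gen.q, size=n_reps)
    pvals = two_proportion_z_pvalue(k1, na, k2, nb)
    est = float(np.mean(pvals < query.alpha))
    se = math.sqrt(est * (1.0 - est) / n_reps)
    return EmpiricalPower(
        estimate=est, std_error=se, n_reps=n_reps, analytic=pt.power, seed=seed
    )
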