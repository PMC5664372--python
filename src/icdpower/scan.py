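"""Power-versus-instances tables: single curves and one-parameter sweeps.

Figures in design reports are produced from these tables (one row per
integer threshold x), exported as tidy CSV so that argmax locations and
monotonicity can be checked numerically rather than by pixel comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .model import (
    CodeAttrition,
    CohortSpec,
    DesignQuery,
    GeneticArchitecture,
    evaluate_design,
)

__all__ = ["CurveTable", "power_curve", "sweep", "sweep_to_frame", "SWEEPABLE"]

SWEEPABLE = ("n1", "m", "delta", "epsilon", "q", "R", "alpha")

_COLUMNS = ["x", "n_x", "f", "s", "N", "ncp", "power"]


@dataclass(frozen=True)
class CurveTable:
    """Power curve over integer thresholds for one fixed parameter set.

    ``rows`` is a DataFrame with columns x, n_x, f, s, N, ncp, power, sorted
    by x; ``meta`` records the full parameter set; ``sweep_label`` /
    ``sweep_value`` identify the varied parameter when part of a sweep.
    """

    rows: pd.DataFrame
    meta: dict = field(default_factory=dict)
    sweep_label: str | None = None
    sweep_value: float | None = None

    @property
    def argmax_x(self) -> int:
        """Integer threshold with the highest power (smallest x on ties)."""
        r = self.rows
        return int(r.loc[r["power"].idxmax(), "x"])

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with sweep_param / sweep_value columns prefixed."""
        out = self.rows.copy()
        out.insert(0, "sweep_value", self.sweep_value)
        out.insert(0, "sweep_param", self.sweep_label)
        return out


def power_curve(
    gen: GeneticArchitecture,
    cohort: CohortSpec,
    attrition: CodeAttrition,
    alpha: float = 0.05,
    x_range: tuple[int, int] = (1, 20),
) -> CurveTable:
    """Evaluate the design at every integer x in ``x_range`` (inclusive)."""
    lo, hi = int(x_range[0]), int(x_range[1])
    if not (1 <= lo <= hi <= 100):
        raise ValueError(f"x_range must satisfy 1 <= lo <= hi <= 100, got {x_range}")
    records = []
    for x in range(lo, hi + 1):
        pt = evaluate_design(gen, cohort, attrition, DesignQuery(x=float(x), alpha=alpha))
        records.append([x, pt.n_x, pt.f, pt.s, pt.N, pt.ncp, pt.power])
    rows = pd.DataFrame(records, columns=_COLUMNS)
    meta = {
        "q": gen.q,
        "R": gen.R,
        "n1": cohort.n1,
        "m": cohort.m,
        "delta": attrition.delta,
        "epsilon": attrition.epsilon,
        "alpha": alpha,
    }
    return CurveTable(rows=rows, meta=meta)


def sweep(
    gen: GeneticArchitecture,
    cohort: CohortSpec,
    attrition: CodeAttrition,
    alpha: float,
    vary: str,
    values: list[float],
    x_range: tuple[int, int] = (1, 20),
) -> list[CurveTable]:
    """One curve per value of the varied parameter, on an identical x grid.

    ``vary`` must be one of n1, m, delta, epsilon, q, R, alpha; invalid
    values for the target parameter surface as the model's own domain errors.
    """
    if vary not in SWEEPABLE:
        raise ValueError(
            f"unknown sweep parameter {vary!r}; valid choices: {', '.join(SWEEPABLE)}"
        )
    if not values:
        raise ValueError("sweep values must be nonempty")
    tables = []
    for v in values:
        g, c, a, al = gen, cohort, attrition, alpha
        if vary == "q":
            g = replace(gen, q=v)
        elif vary == "R":
            g = replace(gen, R=v)
        elif vary == "n1":
            c = replace(cohort, n1=v)
        elif vary == "m":
            c = replace(cohort, m=v)
        elif vary == "delta":
            a = replace(attrition, delta=v)
        elif vary == "epsilon":
            a = replace(attrition, epsilon=v)
        elif vary == "alpha":
            al = v
        tab = power_curve(g, c, a, al, x_range)
        tables.append(replace(tab, sweep_label=vary, sweep_value=v))
    return tables


def sweep_to_frame(tables: list[CurveTable]) -> pd.DataFrame:
    """Concatenate sweep curves into one long-format table for CSV export."""
    return pd.concat([t.to_frame() for t in tables], ignore_index=True)
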