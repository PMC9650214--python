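"""Incremental analysis: ICERs, net monetary benefit, dominance classification."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import CEResult, run_cohort
from .parameters import CohortSpec

__all__ = ["CEComparison", "compare", "nmb", "evaluate_cohort", "results_table"]

_EFFECT_TOL = 1e-12


@dataclass(frozen=True)
class CEComparison:
    """Comparator-minus-reference increments and the resulting ratios.

    ICERs are reported only for genuine cost/effect trade-offs; when one
    strategy dominates (cheaper and more effective) the ``dominance`` label
    replaces the ratio and the ICER fields are None, following standard
    health-economics reporting (a negative ICER is never printed).
    """

    reference: CEResult
    comparator: CEResult
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_per_ly: float | None
    icer_per_qaly: float | None
    dominance: str  # comparator_dominant | reference_dominant | tradeoff


def compare(reference: CEResult, comparator: CEResult) -> CEComparison:
    """Incremental comparison on unrounded totals (comparator - reference)."""
    d_cost = comparator.cost - reference.cost
    d_ly = comparator.ly - reference.ly
    d_qaly = comparator.qaly - reference.qaly

    if d_cost <= 0 and d_qaly >= 0 and (d_cost < 0 or d_qaly > 0):
        dominance = "comparator_dominant"
    elif d_cost >= 0 and d_qaly <= 0 and (d_cost > 0 or d_qaly < 0):
        dominance = "reference_dominant"
    else:
        dominance = "tradeoff"

    def ratio(d_eff):
        if dominance != "tradeoff" or abs(d_eff) < _EFFECT_TOL:
            return None
        return d_cost / d_eff

    return CEComparison(
        reference=reference,
        comparator=comparator,
        delta_cost=d_cost,
        delta_ly=d_ly,
        delta_qaly=d_qaly,
        icer_per_ly=ratio(d_ly),
        icer_per_qaly=ratio(d_qaly),
        dominance=dominance,
    )


def nmb(result: CEResult, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold: wtp * QALYs - cost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * result.qaly - result.cost


def evaluate_cohort(spec: CohortSpec, mode: str = "partitioned_survival") -> CEComparison:
    """Run both arms of a cohort and compare T-DXd against chemotherapy."""
    _, ref = run_cohort(spec.chemo, spec.shared, mode=mode)
    _, comp = run_cohort(spec.tdxd, spec.shared, mode=mode)
    return compare(ref, comp)


def results_table(comparisons: dict[str, CEComparison]) -> pd.DataFrame:
    """Arm-per-row results table (cost, LYs, ICER/LY, QALYs, ICER/QALY) per cohort."""
    rows = []
    for cohort, cmp_ in comparisons.items():
        rows.append(
            {
                "cohort": cohort, "strategy": cmp_.reference.strategy,
                "total_cost": cmp_.reference.cost, "ly": cmp_.reference.ly,
                "icer_per_ly": None, "qaly": cmp_.reference.qaly, "icer_per_qaly": None,
            }
        )
        rows.append(
            {
                "cohort": cohort, "strategy": cmp_.comparator.strategy,
                "total_cost": cmp_.comparator.cost, "ly": cmp_.comparator.ly,
                "icer_per_ly": cmp_.icer_per_ly, "qaly": cmp_.comparator.qaly,
                "icer_per_qaly": cmp_.icer_per_qaly
                if cmp_.dominance == "tradeoff"
                else cmp_.dominance,
            }
        )
    return pd.DataFrame(rows)
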