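"""Hazard-ratio-based survival-curve reconstruction for subgroup analyses.

When a trial reports a subgroup's hazard ratio but not its survival curves,
the subgroup curve can be reconstructed from a reference curve under
proportional hazards: S_new(t) = S_ref(t)**hr. For a Weibull this is exact
and closed-form — the scale multiplies by the hazard ratio, the shape is
unchanged — so the whole cost-effectiveness machinery can be rerun for any
subgroup given its hazard ratio alone.
"""

from __future__ import annotations

from dataclasses import replace

from .economics import CEComparison, compare
from .cohort import run_cohort
from .parameters import CohortSpec, WeibullParams

__all__ = ["reconstruct_from_hr", "subgroup_ce"]


def reconstruct_from_hr(reference: WeibullParams, hr: float) -> WeibullParams:
    """Apply a proportional-hazards ratio to a Weibull: scale *= hr, shape unchanged.

    The median transforms exactly as median_ref * (1/hr)**(1/shape).
    """
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    return WeibullParams(scale=reference.scale * hr, shape=reference.shape)


def subgroup_ce(
    spec: CohortSpec,
    hr_pfs: float,
    hr_os: float | None = None,
    mode: str = "partitioned_survival",
) -> CEComparison:
    """Cost-effectiveness of a subgroup defined by hazard ratios.

    The comparator (T-DXd) arm's PFS curve is rebuilt from the reference
    (chemotherapy) arm's PFS curve and ``hr_pfs``; its OS curve likewise when
    ``hr_os`` is given, otherwise the cohort-level fitted OS curve is kept.
    Costs and utilities are taken unchanged from the cohort inputs.
    """
    tdxd = replace(spec.tdxd, pfs=reconstruct_from_hr(spec.chemo.pfs, hr_pfs))
    if hr_os is not None:
        tdxd = replace(tdxd, os=reconstruct_from_hr(spec.chemo.os, hr_os))
    _, ref = run_cohort(spec.chemo, spec.shared, mode=mode)
    _, comp = run_cohort(tdxd, spec.shared, mode=mode)
    return compare(ref, comp)
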