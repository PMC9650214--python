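"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way analysis sweeps each registered scalar over its (low, high) range with
everything else at base and records the ICER per QALY at both ends. The
probabilistic analysis jointly resamples every registered scalar from its
stated family (beta for probabilities and utilities, gamma for costs, normal
for anthropometrics, uniform for the discount rate), moment-matched to the
base value with sd = (high - low) / (2 * 1.96), and summarizes the resulting
incremental cost / incremental QALY cloud as a cost-effectiveness
acceptability curve.

Randomness contract: one root seed; draw ``i`` uses the independent substream
``numpy.random.SeedSequence([root_seed, i])``, so results are reproducible and
stable under any evaluation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import evaluate_cohort
from .parameters import CohortSpec, DistributionSpec, parameter_registry

__all__ = [
    "TornadoEntry",
    "one_way",
    "calibrate_distribution",
    "Sampler",
    "PSAResult",
    "run_psa",
    "ceac",
]

log = logging.getLogger(__name__)

SD_DIVISOR = 2.0 * 1.96  # (high - low) spans mean +/- 1.96 sd


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity result for a single parameter."""

    pid: str
    low: float
    high: float
    icer_low: float | None
    icer_high: float | None
    span: float | None  # None when either end lost the cost/effect trade-off

    @property
    def ranked(self) -> bool:
        return self.span is not None


def one_way(
    spec: CohortSpec,
    distributions: Mapping[str, DistributionSpec],
    pids: Sequence[str] | None = None,
    mode: str = "partitioned_survival",
) -> list[TornadoEntry]:
    """Tornado sweep: each registered parameter to its range ends, others at base.

    Entries are sorted by ICER span, widest first; parameters whose
    perturbation removes the cost/effect trade-off (ΔQALY <= 0 or dominance)
    are flagged with span None and sorted last.
    """
    registry = parameter_registry(spec)
    if pids is None:
        pids = [pid for pid in registry if pid in distributions]
    entries = []
    for pid in pids:
        d = distributions[pid]
        icers = []
        for value in (d.low, d.high):
            cmp_ = evaluate_cohort(registry[pid].set(spec, value), mode=mode)
            icers.append(cmp_.icer_per_qaly)
        lo, hi = icers
        if lo is None or hi is None:
            log.info("tornado: %s excluded from ranking (dominance at a range end)", pid)
            span = None
        else:
            span = abs(hi - lo)
        entries.append(TornadoEntry(pid, d.low, d.high, lo, hi, span))
    entries.sort(key=lambda e: (not e.ranked, -(e.span or 0.0)))
    return entries


# ---------------------------------------------------------------------------
# distribution calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Sampler:
    """Calibrated sampler for one parameter; frozen to a point mass when sd = 0."""

    pid: str
    family: str
    mean: float
    sd: float
    args: tuple

    def sample(self, rng: np.random.Generator, size=None):
        if self.sd == 0.0:
            return self.mean if size is None else np.full(size, self.mean)
        if self.family == "beta":
            return rng.beta(*self.args, size=size)
        if self.family == "gamma":
            shape, scale = self.args
            return rng.gamma(shape, scale, size=size)
        if self.family == "normal":
            return rng.normal(*self.args, size=size)
        if self.family == "uniform":
            return rng.uniform(*self.args, size=size)
        raise AssertionError(self.family)


def calibrate_distribution(spec: DistributionSpec, sd_divisor: float = SD_DIVISOR) -> Sampler:
    """Moment-match a sampler to (mean, sd) with sd = (high - low) / sd_divisor.

    beta: solves alpha/(alpha+beta) = mean, variance = sd**2 (requires mean in
    (0, 1) and sd**2 < mean(1-mean)); gamma: shape = mean**2/var, scale =
    var/mean; normal: (mean, sd); uniform: exact (low, high) endpoints.
    """
    sd = (spec.high - spec.low) / sd_divisor
    m = spec.mean
    if sd == 0.0:
        return Sampler("", spec.family, m, 0.0, ())
    if spec.family == "beta":
        if not 0.0 < m < 1.0:
            raise ValueError(f"beta mean must lie in (0, 1), got {m}")
        v = sd**2
        if v >= m * (1.0 - m):
            raise ValueError("beta variance too large for the given mean")
        common = m * (1.0 - m) / v - 1.0
        return Sampler("", "beta", m, sd, (m * common, (1.0 - m) * common))
    if spec.family == "gamma":
        if m <= 0:
            raise ValueError("gamma mean must be positive")
        v = sd**2
        return Sampler("", "gamma", m, sd, (m * m / v, v / m))
    if spec.family == "normal":
        return Sampler("", "normal", m, sd, (m, sd))
    if spec.family == "uniform":
        return Sampler("", "uniform", (spec.low + spec.high) / 2.0,
                       (spec.high - spec.low) / np.sqrt(12.0), (spec.low, spec.high))
    raise ValueError(f"unknown family {spec.family!r}")


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSAResult:
    """Joint draws and incremental outcomes of a probabilistic sensitivity run."""

    cohort: str
    seed: int
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    draws: pd.DataFrame  # one row per draw, one column per sampled parameter

    @property
    def n(self) -> int:
        return self.delta_cost.size

    def prob_cost_effective(self, wtp: float) -> float:
        """Fraction of draws with positive incremental net monetary benefit."""
        return float(np.mean(wtp * self.delta_qaly - self.delta_cost > 0.0))

    def as_frame(self, wtp: float = 150_000.0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "draw": np.arange(self.n),
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
                f"inmb_at_{int(wtp)}": wtp * self.delta_qaly - self.delta_cost,
            }
        )


_MAX_RETRIES = 100


def run_psa(
    spec: CohortSpec,
    distributions: Mapping[str, DistributionSpec],
    n_draws: int,
    seed: int,
    sd_divisor: float = SD_DIVISOR,
    mode: str = "partitioned_survival",
) -> PSAResult:
    """Monte-Carlo resampling of all registered scalars; survival curves stay fixed.

    Draws producing invalid model inputs (for example a normal tail pushing a
    utility above 1, or sampled PD utility exceeding sampled PFS utility) are
    resampled with a capped retry count and a log note.
    """
    if n_draws < 1:
        raise ValueError("need at least one draw")
    registry = parameter_registry(spec)
    pids = sorted(pid for pid in registry if pid in distributions)
    samplers = {pid: calibrate_distribution(distributions[pid], sd_divisor) for pid in pids}

    d_cost = np.empty(n_draws)
    d_qaly = np.empty(n_draws)
    records = np.empty((n_draws, len(pids)))
    n_resampled = 0
    for i in range(n_draws):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        for attempt in range(_MAX_RETRIES):
            values = {pid: float(samplers[pid].sample(rng)) for pid in pids}
            trial = spec
            for pid, v in values.items():
                trial = registry[pid].set(trial, v)
            try:
                trial.validate()
            except Exception:
                n_resampled += 1
                continue
            break
        else:
            raise RuntimeError(f"draw {i}: no valid sample within {_MAX_RETRIES} retries")
        cmp_ = evaluate_cohort(trial, mode=mode)
        d_cost[i] = cmp_.delta_cost
        d_qaly[i] = cmp_.delta_qaly
        records[i] = [values[pid] for pid in pids]
    if n_resampled:
        log.info("PSA: %d invalid joint draws were resampled", n_resampled)
    return PSAResult(
        cohort=spec.label,
        seed=seed,
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        draws=pd.DataFrame(records, columns=pids),
    )


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    probs = [psa.prob_cost_effective(w) for w in grid]
    return pd.DataFrame({"wtp": grid, "prob_cost_effective": probs})
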