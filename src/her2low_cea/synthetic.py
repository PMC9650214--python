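"""Synthetic survival-curve pipeline for end-to-end testing of the fitting stage.

Cost-effectiveness models built on published trials rest on a data chain
whose raw inputs are never deposited: Weibull event times -> censoring ->
Kaplan-Meier estimate -> a handful of manually digitized points -> parametric
refit. This module emulates exactly that chain with known ground truth, so
parameter recovery of the survival machinery is testable without any
external data.

Censoring is modelled as an independent exponential dropout plus an
administrative cap at the end of follow-up; digitization picks a sparse set of
points off the step curve (quantile- or time-spaced) with optional additive
noise of stated sd, clipped to [0, 1] and monotonized.
"""

from __future__ import annotations

import warnings

import numpy as np
from lifelines import KaplanMeierFitter

from .parameters import WeibullParams

__all__ = ["simulate_ipd", "km_estimate", "digitize"]


def simulate_ipd(
    p: WeibullParams,
    n: int,
    censor_rate: float = 0.0,
    max_followup: float = np.inf,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw (time, event) individual patient data from a Weibull with censoring.

    Event times use the inverse CDF t = (-ln U / scale)**(1/shape); dropout is
    exponential with ``censor_rate`` per fitted time unit; ``max_followup``
    right-censors administratively. Returns an (n, 2) array with event flag 1
    for observed events.
    """
    if n < 1:
        raise ValueError("need at least one subject")
    if censor_rate < 0:
        raise ValueError("censor rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=n)
    event_times = (-np.log(u) / p.scale) ** (1.0 / p.shape)
    censor_times = np.full(n, float(max_followup))
    if censor_rate > 0:
        censor_times = np.minimum(censor_times, rng.exponential(1.0 / censor_rate, size=n))
    times = np.minimum(event_times, censor_times)
    events = (event_times <= censor_times).astype(float)
    return np.column_stack([times, events])


def km_estimate(ipd: np.ndarray) -> np.ndarray:
    """Product-limit (Kaplan-Meier) estimate as (time, survival) step points.

    Returns the right-continuous step curve evaluated at the observed times,
    starting at (0, 1). An all-censored sample yields a flat curve at 1 with a
    warning.
    """
    ipd = np.asarray(ipd, dtype=float)
    if ipd.ndim != 2 or ipd.shape[1] != 2 or ipd.shape[0] == 0:
        raise ValueError("ipd must be a non-empty (n, 2) array of (time, event)")
    if np.any(ipd[:, 0] < 0):
        raise ValueError("times must be non-negative")
    if ipd[:, 1].sum() == 0:
        warnings.warn("all subjects censored; survival curve is flat at 1", stacklevel=2)
    kmf = KaplanMeierFitter()
    kmf.fit(ipd[:, 0], event_observed=ipd[:, 1])
    sf = kmf.survival_function_
    return np.column_stack([sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy()])


def _step_lookup(curve: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Right-continuous step-function evaluation of a (time, survival) curve."""
    idx = np.searchsorted(curve[:, 0], t, side="right") - 1
    return curve[np.clip(idx, 0, len(curve) - 1), 1]


def digitize(
    curve: np.ndarray,
    k: int = 20,
    mode: str = "quantile",
    noise_sd: float = 0.005,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Emulate manual digitization: ``k`` sparse points off a KM step curve.

    ``quantile`` mode picks points at evenly spaced survival levels between the
    curve's first drop and its minimum (so points concentrate where the curve
    moves); ``time`` mode spaces them evenly over the observed time range.
    Additive Gaussian noise of ``noise_sd`` emulates digitizer error; points
    are clipped to [0, 1] and monotonized. If fewer than ``k`` distinct steps
    exist, the available steps are returned.
    """
    curve = np.asarray(curve, dtype=float)
    if k < 3:
        raise ValueError("need at least 3 points")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    drops = curve[curve[:, 1] < 1.0]
    if drops.shape[0] == 0:
        raise ValueError("curve never drops below 1; nothing to digitize")
    if mode == "quantile":
        levels = np.linspace(drops[:, 1].max(), drops[:, 1].min(), k)
        # first time at which the curve falls to or below each level
        times = np.array([drops[drops[:, 1] <= lv][0, 0] for lv in levels])
        times, keep = np.unique(times, return_index=True)
        pts = np.column_stack([times, _step_lookup(curve, times)])
    elif mode == "time":
        times = np.unique(np.linspace(drops[0, 0], curve[-1, 0], k))
        pts = np.column_stack([times, _step_lookup(curve, times)])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if noise_sd > 0:
        pts[:, 1] = pts[:, 1] + rng.normal(0.0, noise_sd, size=len(pts))
    pts[:, 1] = np.clip(pts[:, 1], 0.0, 1.0)
    pts[:, 1] = np.minimum.accumulate(pts[:, 1])
    # the fitting stage needs survival in (0, 1]: drop points at exactly zero
    return pts[pts[:, 1] > 0.0]
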