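"""Weibull survival machinery.

Parametrization is the hazard scale used throughout health-economic modelling
of trial extrapolations:

    S(t) = exp(-lambda * t**gamma)

with scale ``lambda > 0`` (per fitted-time-unit**gamma) and dimensionless
shape ``gamma > 0``. The per-cycle, time-dependent transition probability of a
Markov cohort model follows from conditional survival over one cycle of
length ``u``:

    tp(t, u) = 1 - S(t) / S(t - u) = 1 - exp(lambda*(t-u)**gamma - lambda*t**gamma)

Fitting supports the two routes used when survival curves are recovered from
published figures: log(-log S) linear regression on the digitized points, and
maximum likelihood on pseudo individual-patient data reconstructed from them.
AIC/BIC model comparison between the Weibull and its exponential special case
is computed on the pseudo-IPD likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special

from .parameters import WeibullParams

__all__ = [
    "weibull_survival",
    "transition_probability",
    "weibull_median",
    "weibull_mean",
    "FitResult",
    "fit_weibull",
    "fit_weibull_mle",
    "pseudo_ipd_from_points",
    "compare_fits",
    "read_curve",
    "write_curve",
]


def weibull_survival(t, p: WeibullParams):
    """Survival probability S(t) = exp(-scale * t**shape); vectorized over t."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = np.exp(-p.scale * t**p.shape)
    return out if out.ndim else float(out)


def transition_probability(t, u: float, p: WeibullParams):
    """Probability of leaving the state during the cycle ending at ``t``.

    ``u`` is the cycle length in fitted time units; equals
    1 - S(t)/S(t-u) = 1 - exp{scale*(t-u)**shape - scale*t**shape}.
    """
    t = np.asarray(t, dtype=float)
    if u <= 0:
        raise ValueError("cycle length u must be positive")
    if np.any(t < u):
        raise ValueError("require t >= u (cycle must end at or after one cycle length)")
    out = 1.0 - np.exp(p.scale * ((t - u) ** p.shape - t**p.shape))
    return out if out.ndim else float(out)


def weibull_median(p: WeibullParams) -> float:
    """Closed-form median (ln 2 / scale)**(1/shape)."""
    return float((np.log(2.0) / p.scale) ** (1.0 / p.shape))


def weibull_mean(p: WeibullParams) -> float:
    """Closed-form mean scale**(-1/shape) * Gamma(1 + 1/shape)."""
    return float(p.scale ** (-1.0 / p.shape) * special.gamma(1.0 + 1.0 / p.shape))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters plus diagnostics for one candidate family."""

    family: str
    params: WeibullParams
    method: str
    n_points: int
    loglik: float | None = None
    n_pseudo: int | None = None
    aic: float | None = None
    bic: float | None = None
    rmse_loglog: float | None = None

    @property
    def n_free_params(self) -> int:
        return 1 if self.family == "exponential" else 2


def _validate_points(points) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (time, survival) points")
    t, s = pts[:, 0], pts[:, 1]
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any((s <= 0) | (s > 1)):
        raise ValueError("survival must lie in (0, 1]")
    if np.any(np.diff(s) > 0):
        raise ValueError("survival must be non-increasing")
    return t, s


def _loglog_fit(t: np.ndarray, s: np.ndarray) -> tuple[WeibullParams, float]:
    """Regress log(-log S) on log t: slope = shape, intercept = log scale."""
    keep = (s < 1.0) & (t > 0)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 usable points after excluding S >= 1")
    x = np.log(t[keep])
    y = np.log(-np.log(s[keep]))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return WeibullParams(scale=float(np.exp(intercept)), shape=float(slope)), rmse


def pseudo_ipd_from_points(
    points, n: int = 500
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct pseudo individual-patient data from digitized curve points.

    Survival drops between consecutive points are converted into event counts
    out of a nominal cohort of size ``n`` (events placed at the interval's end
    time); patients still alive at the last point are right-censored there.
    """
    t, s = _validate_points(points)
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        s = np.concatenate([[1.0], s])
    deaths = np.diff(-s) * n
    counts = np.rint(deaths).astype(int)
    times = np.repeat(t[1:], counts)
    events = np.ones(times.size, dtype=bool)
    n_cens = n - counts.sum()
    if n_cens > 0:
        times = np.concatenate([times, np.full(n_cens, t[-1])])
        events = np.concatenate([events, np.zeros(n_cens, dtype=bool)])
    return times, events


def _weibull_loglik(times: np.ndarray, events: np.ndarray, scale: float, shape: float) -> float:
    t = np.clip(times, 1e-12, None)
    d = events.astype(float)
    return float(
        np.sum(d * (np.log(scale) + np.log(shape) + (shape - 1.0) * np.log(t)))
        - scale * np.sum(t**shape)
    )


def fit_weibull_mle(
    times: Sequence[float],
    events: Sequence[bool],
    init: WeibullParams | None = None,
    tol: float = 1e-8,
) -> tuple[WeibullParams, float]:
    """Weibull maximum likelihood on right-censored data via profile likelihood.

    For fixed shape the scale maximizing the likelihood is closed-form
    (events / sum(t**shape)); the profile is maximized over log-shape with a
    scalar optimizer. Returns (params, maximized log-likelihood).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    d = int(events.sum())
    if d < 1:
        raise ValueError("need at least one event for maximum likelihood")

    def profile_negll(log_shape: float) -> float:
        shape = float(np.exp(log_shape))
        scale = d / np.sum(np.clip(times, 1e-12, None) ** shape)
        return -_weibull_loglik(times, events, scale, shape)

    x0 = float(np.log(init.shape)) if init is not None else 0.0
    res = optimize.minimize_scalar(
        profile_negll,
        bounds=(x0 - 4.0, x0 + 4.0),
        method="bounded",
        options={"xatol": tol},
    )
    shape = float(np.exp(res.x))
    scale = float(d / np.sum(np.clip(times, 1e-12, None) ** shape))
    return WeibullParams(scale=scale, shape=shape), _weibull_loglik(times, events, scale, shape)


def _interval_counts(points, n: int):
    """Pseudo-cohort death counts between adjacent digitized points.

    Returns (edges, deaths, n_censored): ``edges`` starts at 0, ``deaths[i]``
    subjects leave in (edges[i], edges[i+1]], survivors past the last point
    are right-censored there.
    """
    t, s = _validate_points(points)
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        s = np.concatenate([[1.0], s])
    deaths = np.rint(np.diff(-s) * n)
    return t, deaths, n - deaths.sum()


def _interval_loglik(edges, deaths, n_cens, scale: float, shape: float) -> float:
    s = np.exp(-scale * edges**shape)
    probs = np.clip(s[:-1] - s[1:], 1e-300, None)
    return float(np.sum(deaths * np.log(probs)) + n_cens * np.log(max(s[-1], 1e-300)))


def _fit_interval_mle(
    edges, deaths, n_cens, init: WeibullParams, fix_shape: float | None = None,
    tol: float = 1e-8,
):
    """Interval-censored ML over (log scale, log shape); shape fixable to 1."""
    if fix_shape is None:
        res = optimize.minimize(
            lambda x: -_interval_loglik(edges, deaths, n_cens, np.exp(x[0]), np.exp(x[1])),
            [np.log(init.scale), np.log(init.shape)],
            method="Nelder-Mead",
            options={"xatol": tol, "fatol": tol, "maxiter": 5000},
        )
        params = WeibullParams(*np.exp(res.x))
    else:
        res = optimize.minimize_scalar(
            lambda x: -_interval_loglik(edges, deaths, n_cens, np.exp(x), fix_shape),
            bounds=(np.log(init.scale) - 6.0, np.log(init.scale) + 6.0),
            method="bounded",
            options={"xatol": tol},
        )
        params = WeibullParams(float(np.exp(res.x)), fix_shape)
    return params, _interval_loglik(edges, deaths, n_cens, params.scale, params.shape)


def fit_weibull(
    points,
    method: str = "lsq_loglog",
    n_pseudo: int = 500,
) -> FitResult:
    """Fit a Weibull to digitized (time, survival) points.

    ``lsq_loglog``: linear regression of log(-log S) on log t (points with
    S >= 1 excluded; at least 3 must remain).
    ``mle_pseudo_ipd``: maximum likelihood on a pseudo-cohort of ``n_pseudo``
    patients reconstructed from the points. Because the digitized curve only
    locates each event between two adjacent points, the likelihood treats
    events as interval-censored there (survivors right-censored at the last
    point); initialization comes from the log-log estimate.
    """
    t, s = _validate_points(points)
    ll_params, rmse = _loglog_fit(t, s)
    if method == "lsq_loglog":
        return FitResult(
            family="weibull", params=ll_params, method=method,
            n_points=len(t), rmse_loglog=rmse,
        )
    if method == "mle_pseudo_ipd":
        edges, deaths, n_cens = _interval_counts(np.column_stack([t, s]), n_pseudo)
        params, loglik = _fit_interval_mle(edges, deaths, n_cens, init=ll_params)
        k = 2
        return FitResult(
            family="weibull", params=params, method=method, n_points=len(t),
            loglik=loglik, n_pseudo=n_pseudo,
            aic=2 * k - 2 * loglik, bic=k * np.log(n_pseudo) - 2 * loglik,
            rmse_loglog=rmse,
        )
    raise ValueError(f"unknown method {method!r}")


def compare_fits(
    points,
    families: Sequence[str] = ("weibull", "exponential"),
    n_pseudo: int = 500,
) -> list[FitResult]:
    """Rank candidate parametric families by AIC/BIC on the pseudo-cohort likelihood.

    Both families are fitted by interval-censored maximum likelihood on the
    same reconstructed pseudo-cohort, so their criteria are comparable. Lower
    is better; ties (within 1e-9) break toward fewer parameters. Returns
    FitResults sorted best first.
    """
    t, s = _validate_points(points)
    edges, deaths, n_cens = _interval_counts(np.column_stack([t, s]), n_pseudo)
    init, _ = _loglog_fit(t, s)
    results = []
    for family in families:
        if family == "weibull":
            params, loglik = _fit_interval_mle(edges, deaths, n_cens, init=init)
            k = 2
        elif family == "exponential":
            params, loglik = _fit_interval_mle(edges, deaths, n_cens, init=init, fix_shape=1.0)
            k = 1
        else:
            raise ValueError(f"unknown family {family!r}")
        results.append(
            FitResult(
                family=family, params=params, method="mle_pseudo_ipd",
                n_points=len(t), loglik=loglik, n_pseudo=n_pseudo,
                aic=2 * k - 2 * loglik, bic=k * np.log(n_pseudo) - 2 * loglik,
            )
        )
    results.sort(key=lambda r: (round(r.aic, 9), r.n_free_params))
    return results


# ---------------------------------------------------------------------------
# digitized-curve file format: two columns (time, survival), '#' comments
# ---------------------------------------------------------------------------


def read_curve(path) -> np.ndarray:
    """Read a digitized curve file: header line then two delimited columns."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", "\t").split()
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except (ValueError, IndexError):
                if not rows:  # header line
                    continue
                raise ValueError(f"unparseable curve line {i + 1}: {line!r}")
    return np.asarray(rows, dtype=float)


def write_curve(path, points, comment: str | None = None) -> None:
    pts = np.asarray(points, dtype=float)
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("time\tsurvival\n")
        for t, s in pts:
            fh.write(f"{t:.10g}\t{s:.10g}\n")
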