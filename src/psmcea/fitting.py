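"""Fitting parametric survival models to censored data and digitized curves.

Two routes produce the extrapolation curves the cohort model consumes:

* maximum likelihood on (pseudo) individual-patient data with right
  censoring — the right-censored log-likelihood
  ``sum_events log f(t) + sum_censored log S(t)`` is maximized in
  log-parameter space with a multi-start quasi-Newton optimizer;
* least squares on digitized Kaplan-Meier coordinates, mirroring the
  digitize-then-fit workflow used when only published figures are
  available.

Candidate families are ranked by AIC (ties: BIC, then family name), the
standard information-criterion selection for survival extrapolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .distributions import FAMILIES, PARAM_NAMES, _UNCONSTRAINED, ParametricDistribution
from .exceptions import (
    ConvergenceError,
    DomainError,
    FlatCurveError,
    IncomparableFitsError,
    InsufficientEventsError,
)


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's follow-up: time in cycles and an event flag.

    ``event`` is 1 when the endpoint was observed and 0 when the subject
    was right-censored at ``time``.
    """

    time: float
    event: int

    def __post_init__(self):
        if self.time < 0:
            raise DomainError(f"time must be >= 0, got {self.time}")
        if self.event not in (0, 1):
            raise DomainError(f"event must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class DigitizedCurve:
    """Ordered (time, survival) coordinates read off a survival figure."""

    times: tuple[float, ...]
    survival: tuple[float, ...]

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if t.ndim != 1 or t.shape != s.shape:
            raise DomainError("times and survival must be equal-length vectors")
        if len(t) and np.any(np.diff(t) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any((s < 0) | (s > 1)):
            raise DomainError("survival values must lie in [0, 1]")
        if len(s) and np.any(np.diff(s) > 1e-12):
            raise DomainError("survival values must be nonincreasing")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "survival", tuple(float(x) for x in s))

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_cycles": self.times, "survival": self.survival})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DigitizedCurve":
        df = pd.read_csv(path)
        return cls(tuple(df["time_cycles"]), tuple(df["survival"]))


def records_to_frame(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    records = list(records)
    return pd.DataFrame(
        {
            "time_cycles": [r.time for r in records],
            "event": [r.event for r in records],
        }
    )


def records_from_frame(df: pd.DataFrame) -> list[SurvivalRecord]:
    return [
        SurvivalRecord(float(t), int(e))
        for t, e in zip(df["time_cycles"], df["event"])
    ]


def records_to_csv(records: Iterable[SurvivalRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def records_from_csv(path) -> list[SurvivalRecord]:
    return records_from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class FitResult:
    """A fitted distribution with its information criteria.

    ``aic = 2k - 2 loglik`` and ``bic = k ln(n_obs) - 2 loglik`` with ``k``
    free parameters.  When ``curve_based`` is true the log-likelihood is a
    Gaussian pseudo-value computed from the residual sum of squares of a
    curve fit and is comparable only across curve-based fits on the same
    points.
    """

    distribution: ParametricDistribution
    loglik: float
    aic: float
    bic: float
    n_obs: int
    curve_based: bool = False


def _make_fit_result(dist, loglik, n_obs, curve_based=False) -> FitResult:
    k = dist.n_params
    return FitResult(
        distribution=dist,
        loglik=loglik,
        aic=2.0 * k - 2.0 * loglik,
        bic=k * math.log(n_obs) - 2.0 * loglik,
        n_obs=n_obs,
        curve_based=curve_based,
    )


# -- parameter transforms -------------------------------------------------

def _to_unconstrained(family: str, values: np.ndarray) -> np.ndarray:
    out = values.copy()
    for i, name in enumerate(PARAM_NAMES[family]):
        if (family, name) not in _UNCONSTRAINED:
            out[i] = math.log(values[i])
    return out


def _from_unconstrained(family: str, theta: np.ndarray) -> dict[str, float]:
    out = {}
    for i, name in enumerate(PARAM_NAMES[family]):
        if (family, name) in _UNCONSTRAINED:
            out[name] = float(theta[i])
        else:
            out[name] = float(math.exp(np.clip(theta[i], -50.0, 50.0)))
    return out


def _initial_params(family: str, times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Moment-flavoured starting values; crude on purpose (multi-start)."""
    total_time = max(times.sum(), 1e-12)
    rate = max(events.sum(), 1.0) / total_time
    obs = times[events == 1]
    med = float(np.median(obs)) if len(obs) else 1.0 / rate
    med = max(med, 1e-6)
    if family == "weibull":
        return np.array([1.0, rate])
    if family == "exponential":
        return np.array([rate])
    if family == "gamma":
        return np.array([1.0, rate])
    if family == "lognormal":
        logs = np.log(np.maximum(obs, 1e-12)) if len(obs) else np.array([0.0])
        return np.array([float(np.mean(logs)), max(float(np.std(logs)), 0.25)])
    if family == "loglogistic":
        return np.array([med, 1.5])
    # gompertz: small positive shape, exponential-like rate
    return np.array([0.05, rate])


def _neg_loglik(theta, family, times, events):
    params = _from_unconstrained(family, np.asarray(theta, dtype=float))
    try:
        dist = ParametricDistribution(family, params)
    except DomainError:
        return 1e12
    with np.errstate(over="ignore", invalid="ignore"):
        ll_event = dist.logpdf(times[events == 1])
        ll_cens = -dist.cumulative_hazard(times[events == 0])
    total = float(np.sum(ll_event) + np.sum(ll_cens))
    if not math.isfinite(total):
        return 1e12
    return -total


def fit_mle(
    data: Sequence[SurvivalRecord],
    family: str,
    n_starts: int = 3,
    tol: float = 1e-8,
) -> FitResult:
    """Maximum-likelihood fit of ``family`` to right-censored records.

    Optimizes in log-parameter space (unconstrained), from ``n_starts``
    perturbed moment-based starting points, keeping the best optimum.
    Raises :class:`InsufficientEventsError` with fewer than two observed
    events and :class:`ConvergenceError` when no start converges.
    """
    if family not in FAMILIES:
        raise DomainError(f"unknown family {family!r}")
    data = list(data)
    times = np.array([r.time for r in data], dtype=float)
    events = np.array([r.event for r in data], dtype=int)
    if events.sum() < 2:
        raise InsufficientEventsError(
            f"need >= 2 observed events to fit {family}, got {int(events.sum())}"
        )
    # events recorded exactly at t=0 carry no density information
    times = np.where((events == 1) & (times <= 0), 1e-8, times)

    theta0 = _to_unconstrained(family, _initial_params(family, times, events))
    rng = np.random.default_rng(0)  # fixed deterministic perturbations
    best = None
    diagnostics = []
    for start in range(n_starts):
        theta_start = theta0 if start == 0 else theta0 + rng.normal(0, 0.5, theta0.shape)
        res = optimize.minimize(
            _neg_loglik,
            theta_start,
            args=(family, times, events),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": tol, "maxiter": 4000},
        )
        diagnostics.append(res)
        if res.fun < 1e11 and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise ConvergenceError(
            f"MLE for {family} failed to converge from {n_starts} starts",
            diagnostics=diagnostics,
        )
    dist = ParametricDistribution(family, _from_unconstrained(family, best.x))
    return _make_fit_result(dist, -float(best.fun), n_obs=len(data))


def fit_to_curve(
    points: DigitizedCurve,
    family: str,
    loss: str = "squared-survival",
) -> FitResult:
    """Least-squares fit of a family's S(t) to digitized curve points.

    ``loss`` is squared error on the survival scale (default) or on the
    complementary log-log scale ``log(-log S)`` (points with S in (0,1)
    only).  The returned information criteria are Gaussian pseudo-values
    flagged ``curve_based``.
    """
    if family not in FAMILIES:
        raise DomainError(f"unknown family {family!r}")
    if loss not in ("squared-survival", "complementary-log-log"):
        raise DomainError(f"unknown loss {loss!r}")
    t = np.asarray(points.times, dtype=float)
    s = np.asarray(points.survival, dtype=float)
    keep = s > 0 if loss == "squared-survival" else (s > 0) & (s < 1)
    t, s = t[keep], s[keep]
    # anchor points at t=0 (S=1 by construction) carry no information
    pos = t > 0
    t, s = t[pos], s[pos]
    if len(t) < 3:
        raise DomainError("need >= 3 points with survival in (0, 1] and t > 0")
    if np.all(s >= 1.0 - 1e-12):
        raise FlatCurveError("all survival values are 1; curve carries no signal")

    pseudo_events = np.ones_like(t, dtype=int)
    theta0 = _to_unconstrained(family, _initial_params(family, t, pseudo_events))

    def residuals(theta):
        params = _from_unconstrained(family, np.asarray(theta, dtype=float))
        try:
            dist = ParametricDistribution(family, params)
        except DomainError:
            return np.full_like(s, 1e6)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            if loss == "squared-survival":
                r = dist.survival(t) - s
            else:
                r = np.log(dist.cumulative_hazard(t)) - np.log(-np.log(s))
        return np.nan_to_num(r, nan=1e6, posinf=1e6, neginf=-1e6)

    res = optimize.least_squares(residuals, theta0, xtol=1e-12, ftol=1e-12)
    if not res.success:
        raise ConvergenceError(
            f"curve fit for {family} did not converge: {res.message}",
            diagnostics=res,
        )
    dist = ParametricDistribution(family, _from_unconstrained(family, res.x))
    m = len(t)
    rss = max(float(np.sum(residuals(res.x) ** 2)), 1e-300)
    pseudo_ll = -0.5 * m * (math.log(2.0 * math.pi * rss / m) + 1.0)
    return _make_fit_result(dist, pseudo_ll, n_obs=m, curve_based=True)


def select_model(fits: Sequence[FitResult]) -> list[FitResult]:
    """Rank candidate fits ascending by AIC (ties: BIC, then family name).

    All fits must come from the same data (same ``n_obs`` and the same
    fitting route), otherwise their criteria are not comparable.
    """
    fits = list(fits)
    if not fits:
        raise DomainError("need at least one fit")
    n0, c0 = fits[0].n_obs, fits[0].curve_based
    for f in fits[1:]:
        if f.n_obs != n0 or f.curve_based != c0:
            raise IncomparableFitsError(
                "fits were computed on different data and cannot be ranked"
            )
    return sorted(fits, key=lambda f: (f.aic, f.bic, f.distribution.family))
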