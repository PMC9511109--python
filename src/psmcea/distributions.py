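"""Parametric survival distributions in the rate parameterization.

The cohort model extrapolates overall and progression-free survival with
two-parameter families fitted to reconstructed trial curves.  The Weibull
family — the one retained for both endpoints of both arms — is written in
the *rate* form

    S(t) = exp(-lambda * t**gamma)

with shape ``gamma`` (dimensionless) and scale-rate ``lambda`` (per
cycle**gamma); time is measured in model cycles of 21 days.  Five further
families (exponential, gamma, log-normal, log-logistic, Gompertz) are
available for AIC/BIC model selection.  Parameterizations:

========== ===================== =========================================
family     params                survival function
========== ===================== =========================================
weibull    shape g, rate l       exp(-l * t**g)
exponential rate l               exp(-l * t)
gamma      shape a, rate b       1 - GammaCDF(t; a, rate b)
lognormal  meanlog m, sdlog s    1 - Phi((ln t - m) / s)
loglogistic scale a, shape b     1 / (1 + (t / a)**b)
gompertz   shape a, rate b       exp(-(b / a) * (exp(a * t) - 1))
========== ===================== =========================================

``meanlog`` may be any real; every other parameter must be strictly
positive.  Conversions to the scale-form Weibull convention used by other
software are provided by :func:`weibull_rate_to_scale` and its inverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import integrate, optimize, special, stats

from .exceptions import DomainError, NoMedianError

FAMILIES = ("weibull", "exponential", "gamma", "lognormal", "loglogistic", "gompertz")

#: parameter names per family, in canonical order
PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "weibull": ("shape", "rate"),
    "exponential": ("rate",),
    "gamma": ("shape", "rate"),
    "lognormal": ("meanlog", "sdlog"),
    "loglogistic": ("scale", "shape"),
    "gompertz": ("shape", "rate"),
}

#: parameters allowed to take any real value (all others must be > 0)
_UNCONSTRAINED = {("lognormal", "meanlog")}


def _validate(family: str, params: Mapping[str, float]) -> dict[str, float]:
    if family not in FAMILIES:
        raise DomainError(f"unknown family {family!r}; expected one of {FAMILIES}")
    names = PARAM_NAMES[family]
    if set(params) != set(names):
        raise DomainError(
            f"{family} expects parameters {names}, got {tuple(params)}"
        )
    out = {}
    for name in names:
        value = float(params[name])
        if not math.isfinite(value):
            raise DomainError(f"{family} parameter {name!r} is not finite")
        if (family, name) not in _UNCONSTRAINED and value <= 0:
            raise DomainError(f"{family} parameter {name!r} must be > 0, got {value}")
        out[name] = value
    return out


@dataclass(frozen=True)
class ParametricDistribution:
    """A survival family with fixed parameters on the model's cycle grid.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    params : mapping
        Family-specific parameters, see module docstring.
    time_unit : str
        Label for the time axis; the cohort model uses 21-day cycles.
    """

    family: str
    params: Mapping[str, float]
    time_unit: str = "cycle (21 days)"

    def __post_init__(self):
        object.__setattr__(self, "params", _validate(self.family, self.params))

    # -- constructors -----------------------------------------------------
    @classmethod
    def weibull(cls, shape: float, rate: float, **kw) -> "ParametricDistribution":
        return cls("weibull", {"shape": shape, "rate": rate}, **kw)

    @classmethod
    def exponential(cls, rate: float, **kw) -> "ParametricDistribution":
        return cls("exponential", {"rate": rate}, **kw)

    @property
    def n_params(self) -> int:
        return len(PARAM_NAMES[self.family])

    def _p(self, name: str) -> float:
        return self.params[name]

    # -- core quantities --------------------------------------------------
    def cumulative_hazard(self, t):
        """H(t) with S(t) = exp(-H(t)); vectorized over ``t``."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise DomainError("t must be >= 0")
        f, p = self.family, self.params
        if f == "weibull":
            return p["rate"] * t ** p["shape"]
        if f == "exponential":
            return p["rate"] * t
        if f == "gamma":
            return -stats.gamma.logsf(t, a=p["shape"], scale=1.0 / p["rate"])
        if f == "lognormal":
            return -stats.lognorm.logsf(t, s=p["sdlog"], scale=math.exp(p["meanlog"]))
        if f == "loglogistic":
            return np.log1p((t / p["scale"]) ** p["shape"])
        # gompertz; overflow at extreme t just saturates H at +inf (S=0)
        a, b = p["shape"], p["rate"]
        with np.errstate(over="ignore"):
            return (b / a) * np.expm1(a * t)

    def survival(self, t):
        """S(t); S(0) = 1 exactly for every family."""
        return np.exp(-self.cumulative_hazard(t))

    def logpdf(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise DomainError("t must be >= 0")
        f, p = self.family, self.params
        with np.errstate(divide="ignore"):
            if f == "weibull":
                g, l = p["shape"], p["rate"]
                return np.log(l * g) + (g - 1.0) * np.log(t) - l * t ** g
            if f == "exponential":
                return math.log(p["rate"]) - p["rate"] * t
            if f == "gamma":
                return stats.gamma.logpdf(t, a=p["shape"], scale=1.0 / p["rate"])
            if f == "lognormal":
                return stats.lognorm.logpdf(
                    t, s=p["sdlog"], scale=math.exp(p["meanlog"])
                )
            if f == "loglogistic":
                return stats.fisk.logpdf(t, c=p["shape"], scale=p["scale"])
            a, b = p["shape"], p["rate"]
            return math.log(b) + a * t - (b / a) * np.expm1(a * t)

    def quantile(self, q):
        """Time t with F(t) = q, i.e. S(t) = 1 - q (closed form per family)."""
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q >= 1)):
            raise DomainError("quantile level must be in [0, 1)")
        f, p = self.family, self.params
        if f == "weibull":
            return (-np.log1p(-q) / p["rate"]) ** (1.0 / p["shape"])
        if f == "exponential":
            return -np.log1p(-q) / p["rate"]
        if f == "gamma":
            return stats.gamma.ppf(q, a=p["shape"], scale=1.0 / p["rate"])
        if f == "lognormal":
            return stats.lognorm.ppf(q, s=p["sdlog"], scale=math.exp(p["meanlog"]))
        if f == "loglogistic":
            return stats.fisk.ppf(q, c=p["shape"], scale=p["scale"])
        a, b = p["shape"], p["rate"]
        return np.log1p(-(a / b) * np.log1p(-q)) / a

    def mean(self) -> float:
        """Unrestricted mean survival time, analytic where available."""
        f, p = self.family, self.params
        if f == "weibull":
            g, l = p["shape"], p["rate"]
            return l ** (-1.0 / g) * special.gamma(1.0 + 1.0 / g)
        if f == "exponential":
            return 1.0 / p["rate"]
        if f == "gamma":
            return p["shape"] / p["rate"]
        if f == "lognormal":
            return math.exp(p["meanlog"] + 0.5 * p["sdlog"] ** 2)
        if f == "loglogistic":
            b = p["shape"]
            if b <= 1:
                return math.inf
            return p["scale"] * math.pi / (b * math.sin(math.pi / b))
        value, _ = integrate.quad(lambda t: float(self.survival(t)), 0, np.inf)
        return value


def survival_at(dist: ParametricDistribution, t) -> float | np.ndarray:
    """Evaluate S(t); thin functional wrapper over ``dist.survival``."""
    out = dist.survival(t)
    return float(out) if np.ndim(out) == 0 else out


def median_survival(dist: ParametricDistribution) -> float:
    """Time at which S(t) = 0.5.

    Closed-form inverse where the family has one; a bracketed Brent root on
    S(t) - 0.5 (relative tolerance 1e-8) otherwise.  Raises
    :class:`NoMedianError` when the survival function stays above 0.5 on
    the whole search bracket.
    """
    try:
        m = float(dist.quantile(0.5))
        if math.isfinite(m):
            return m
    except (DomainError, ValueError):
        pass
    upper = 1.0
    while dist.survival(upper) > 0.5:
        upper *= 2.0
        if upper > 1e12:
            raise NoMedianError(
                f"{dist.family} survival exceeds 0.5 on the whole bracket"
            )
    return optimize.brentq(
        lambda t: float(dist.survival(t)) - 0.5, 0.0, upper, rtol=1e-8
    )


def restricted_mean_survival(
    dist: ParametricDistribution, horizon: float, rule: str = "quad"
) -> float:
    """Restricted mean survival time: integral of S(t) on [0, horizon].

    ``rule`` is either adaptive quadrature (``"quad"``) or a trapezoid rule
    on 4,096 evenly spaced nodes (``"trapezoid"``).  Converges to the
    analytic mean as the horizon grows.
    """
    if horizon < 0:
        raise DomainError("horizon must be >= 0")
    if horizon == 0:
        return 0.0
    if rule == "quad":
        value, _ = integrate.quad(
            lambda t: float(dist.survival(t)), 0.0, horizon, limit=500
        )
        return value
    if rule == "trapezoid":
        grid = np.linspace(0.0, horizon, 4097)
        return float(np.trapezoid(dist.survival(grid), grid))
    raise DomainError(f"unknown integration rule {rule!r}")


def weibull_rate_to_scale(shape: float, rate: float) -> tuple[float, float]:
    """Convert rate-form (shape, rate) to scale-form (shape, scale).

    Scale-form: S(t) = exp(-(t / scale)**shape), so scale = rate**(-1/shape).
    """
    return shape, rate ** (-1.0 / shape)


def weibull_scale_to_rate(shape: float, scale: float) -> tuple[float, float]:
    """Inverse of :func:`weibull_rate_to_scale`."""
    return shape, scale ** (-shape)
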