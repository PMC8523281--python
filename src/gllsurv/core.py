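"""Closed-form properties of the generalized log-logistic (GLL) distribution.

The GLL is a three-parameter lifetime distribution with hazard

    h(x) = alpha * kappa * (kappa x)^(alpha-1) / (1 + (eta x)^alpha),

so the survival function is S(x) = (1 + (eta x)^alpha)^(-c) with
c = (kappa/eta)^alpha.  For alpha <= 1 the hazard is non-increasing; for
alpha > 1 it is unimodal with mode (alpha-1)^(1/alpha) / eta.  The family
nests the log-logistic (kappa = eta), the standard log-logistic
(kappa = eta = 1), the Burr XII (eta = kappa * lambda^(-1/alpha)), the
Weibull (eta^alpha -> 0) and the exponential (additionally alpha = 1).

All expressions are evaluated in log space so that extreme values of
c = (kappa/eta)^alpha (easily ~1e5 for moderate parameters) do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "GLLParams",
    "MomentNotDefinedError",
    "hazard",
    "pdf",
    "logpdf",
    "survival",
    "cdf",
    "reversed_hazard",
    "cumulative_hazard",
    "hazard_rate_average",
    "hazard_mode",
    "quantile",
    "random_sample",
    "raw_moment",
    "negative_moment",
    "mean_variance",
    "cumulants_and_shape",
    "galton_moors",
    "residual_life_sf",
    "reversed_residual_life_sf",
]


class MomentNotDefinedError(ValueError):
    """Raised when a requested moment does not exist.

    E[T^r] is finite only when alpha * (kappa/eta)^alpha > r; outside that
    region the defining integral diverges (the density tail decays like
    x^(-1 - alpha * c)).
    """


@dataclass(frozen=True)
class GLLParams:
    """Parameter triple (alpha, kappa, eta) of the GLL distribution.

    alpha : dimensionless shape exponent, > 0
    kappa : primary rate (1/time), > 0
    eta   : tail rate (1/time), > 0
    """

    alpha: float
    kappa: float
    eta: float

    def __post_init__(self) -> None:
        for name in ("alpha", "kappa", "eta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    @property
    def log_c(self) -> float:
        """log of c = (kappa/eta)^alpha."""
        return self.alpha * (np.log(self.kappa) - np.log(self.eta))

    @property
    def c(self) -> float:
        return float(np.exp(self.log_c))

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.kappa, self.eta])


def _check_x(x, allow_zero: bool = True) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("times must be non-negative")
    if not allow_zero and np.any(x == 0):
        raise ValueError("times must be strictly positive here")
    return x


def _log1p_u(p: GLLParams, x: np.ndarray) -> np.ndarray:
    """log(1 + (eta x)^alpha), stable for large and tiny (eta x)^alpha."""
    with np.errstate(divide="ignore"):
        lu = p.alpha * (np.log(p.eta) + np.log(x))
    return np.logaddexp(0.0, lu)


def hazard(params: GLLParams, x) -> np.ndarray | float:
    """Hazard rate h(x) = alpha k (k x)^(alpha-1) / (1 + (eta x)^alpha).

    At x = 0 the analytic limit is returned: 0 for alpha > 1, kappa for
    alpha = 1, and +inf for alpha < 1.
    """
    x = _check_x(x)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.empty_like(x)
    zero = x == 0
    if params.alpha > 1:
        out[zero] = 0.0
    elif params.alpha == 1:
        out[zero] = params.kappa
    else:
        out[zero] = np.inf
    xp = x[~zero]
    log_h = (
        np.log(params.alpha)
        + params.alpha * np.log(params.kappa)
        + (params.alpha - 1) * np.log(xp)
        - _log1p_u(params, xp)
    )
    out[~zero] = np.exp(log_h)
    return float(out[0]) if scalar else out


def hazard_mode(params: GLLParams) -> float:
    """Mode of the hazard for alpha > 1: (alpha - 1)^(1/alpha) / eta."""
    if params.alpha <= 1:
        raise ValueError("hazard is non-increasing for alpha <= 1; no interior mode")
    return (params.alpha - 1) ** (1 / params.alpha) / params.eta


def logpdf(params: GLLParams, x) -> np.ndarray | float:
    x = _check_x(x)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.empty_like(x)
    zero = x == 0
    if params.alpha > 1:
        out[zero] = -np.inf
    elif params.alpha == 1:
        out[zero] = np.log(params.kappa)
    else:
        out[zero] = np.inf
    xp = x[~zero]
    c = np.exp(params.log_c)
    out[~zero] = (
        np.log(params.alpha)
        + params.alpha * np.log(params.kappa)
        + (params.alpha - 1) * np.log(xp)
        - (c + 1) * _log1p_u(params, xp)
    )
    return float(out[0]) if scalar else out


def pdf(params: GLLParams, x) -> np.ndarray | float:
    """Density f(x) = alpha k (k x)^(alpha-1) (1 + (eta x)^alpha)^(-(c+1))."""
    return np.exp(logpdf(params, x))


def log_survival(params: GLLParams, x) -> np.ndarray | float:
    x = _check_x(x)
    c = np.exp(params.log_c)
    return -c * _log1p_u(params, x)


def survival(params: GLLParams, x) -> np.ndarray | float:
    """Survival S(x) = (1 + (eta x)^alpha)^(-c), c = (kappa/eta)^alpha."""
    out = np.exp(log_survival(params, x))
    return float(out) if np.ndim(out) == 0 else out


def cdf(params: GLLParams, x) -> np.ndarray | float:
    """Lifetime distribution function F = 1 - S."""
    out = -np.expm1(log_survival(params, x))
    return float(out) if np.ndim(out) == 0 else out


def reversed_hazard(params: GLLParams, x) -> np.ndarray | float:
    """Reversed (retro) hazard r(x) = f(x) / F(x), defined for x > 0."""
    x = _check_x(x, allow_zero=False)
    with np.errstate(divide="ignore"):
        out = np.exp(logpdf(params, x) - np.log(cdf(params, x)))
    return float(out) if np.ndim(x) == 0 else out


def cumulative_hazard(params: GLLParams, x) -> np.ndarray | float:
    """Cumulative hazard H(x) = c * log(1 + (eta x)^alpha) = -log S(x)."""
    x = _check_x(x)
    c = np.exp(params.log_c)
    out = c * _log1p_u(params, x)
    return float(out) if np.ndim(out) == 0 else out


def hazard_rate_average(params: GLLParams, x) -> np.ndarray | float:
    """Hazard rate average HRA(x) = H(x) / x, x > 0."""
    x = _check_x(x, allow_zero=False)
    out = cumulative_hazard(params, x) / x
    return float(out) if np.ndim(x) == 0 else out


def quantile(params: GLLParams, p) -> np.ndarray | float:
    """Quantile function Q(p) = ((1/(1-p))^(1/c) - 1)^(1/alpha) / eta.

    Defined for p in [0, 1); diverges as p -> 1.  Q(0) = 0.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("probability level must lie in [0, 1)")
    c = np.exp(params.log_c)
    # log of (1/(1-p))^(1/c) - 1 = expm1(s), s = -log1p(-p)/c, kept in log
    # space so that heavy-tailed triples (tiny c) do not overflow
    s = -np.log1p(-p) / c
    with np.errstate(divide="ignore"):
        log_t = np.where(s > 30, s, np.log(np.expm1(np.minimum(s, 30.0))))
    out = np.exp(log_t / params.alpha) / params.eta
    return float(out) if np.ndim(out) == 0 else out


def random_sample(params: GLLParams, n: int, seed=None) -> np.ndarray:
    """Draw n variates by inverse-CDF transform of uniforms.

    `seed` may be an int or a numpy Generator; reproducible given a seed.
    """
    if n < 1:
        raise ValueError("sample size must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.uniform(size=int(n))
    return np.asarray(quantile(params, u))


# ---------------------------------------------------------------------------
# moments


def _check_moment_order(r) -> float:
    r = float(r)
    if r <= 0:
        raise ValueError("moment order must be > 0")
    return r


def raw_moment(params: GLLParams, r) -> float:
    """E[T^r] = Gamma(r/alpha + 1) Gamma(c - r/alpha) / (eta^r Gamma(c)).

    Exists iff alpha * c > r (equivalently alpha * kappa^alpha / eta^alpha > r).
    Evaluated through log-gamma differences so that huge c does not overflow.
    """
    r = _check_moment_order(r)
    a, c = params.alpha, np.exp(params.log_c)
    if a * c <= r:
        raise MomentNotDefinedError(
            f"E[T^{r}] does not exist: requires alpha*(kappa/eta)^alpha > r "
            f"but alpha*c = {a * c:.6g}"
        )
    log_m = (
        special.gammaln(r / a + 1)
        + special.gammaln(c - r / a)
        - special.gammaln(c)
        - r * np.log(params.eta)
    )
    return float(np.exp(log_m))


def negative_moment(params: GLLParams, r) -> float:
    """E[T^-r] = eta^r Gamma(1 - r/alpha) Gamma(c + r/alpha) / Gamma(c).

    Converges iff r < alpha (behaviour near zero); validated against
    quadrature of x^(-r) f(x).
    """
    r = _check_moment_order(r)
    a, c = params.alpha, np.exp(params.log_c)
    if r >= a:
        raise MomentNotDefinedError(
            f"E[T^-{r}] does not exist: requires r < alpha (= {a})"
        )
    log_m = (
        r * np.log(params.eta)
        + special.gammaln(1 - r / a)
        + special.gammaln(c + r / a)
        - special.gammaln(c)
    )
    return float(np.exp(log_m))


def mean_variance(params: GLLParams) -> tuple[float, float]:
    """(mean, variance); requires alpha*c > 1 (mean) and > 2 (variance)."""
    m1 = raw_moment(params, 1)
    m2 = raw_moment(params, 2)
    return m1, m2 - m1 * m1


def cumulants_and_shape(params: GLLParams) -> dict[str, float]:
    """First four cumulants plus moment skewness c3/sigma^3 and kurtosis c4/sigma^4.

    Central moments come from the raw moments through the binomial expansion;
    kurtosis here is the plain (non-excess) ratio, matching the convention in
    which the normal distribution scores 3.
    """
    m = [raw_moment(params, r) for r in (1, 2, 3, 4)]
    m1, m2, m3, m4 = m
    c1 = m1
    c2 = m2 - m1**2
    c3 = m3 - 3 * m1 * m2 + 2 * m1**3
    c4 = m4 - 4 * m1 * m3 + 6 * m1**2 * m2 - 3 * m1**4
    sd = np.sqrt(c2)
    return {
        "c1": c1,
        "c2": c2,
        "c3": c3,
        "c4": c4,
        "sd": float(sd),
        "skewness": float(c3 / sd**3),
        "kurtosis": float(c4 / sd**4),
    }


def galton_moors(params: GLLParams) -> tuple[float, float]:
    """Quantile-based (Galton) skewness and (Moors) kurtosis.

    These exist for every valid parameter triple, even when the moments do not.
    """
    q = quantile(params, np.arange(1, 8) / 8.0)
    sk = (q[5] + q[1] - 2 * q[3]) / (q[5] - q[1])
    km = (q[6] + q[2] - q[4] - q[0]) / (q[5] - q[1])
    return float(sk), float(km)


def residual_life_sf(params: GLLParams, t, x) -> np.ndarray | float:
    """P(T > t + x | T > t) = S(t + x) / S(t)."""
    t = _check_x(t)
    x = _check_x(x)
    out = np.exp(log_survival(params, t + x) - log_survival(params, t))
    return float(out) if np.ndim(out) == 0 else out


def reversed_residual_life_sf(params: GLLParams, t, x, *, repaired: bool = True):
    """Reversed residual life ratio.

    With ``repaired=True`` (default) returns S(t - x)/S(t) for 0 <= x <= t,
    which is well defined on positive support; the literal printed form
    S(x - t)/S(t) is undefined for x < t and is only available with
    ``repaired=False`` when x >= t.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if repaired:
        if np.any(x < 0) or np.any(x > t):
            raise ValueError("repaired convention requires 0 <= x <= t")
        out = np.exp(log_survival(params, t - x) - log_survival(params, t))
    else:
        if np.any(x < t):
            raise ValueError("literal convention requires x >= t (else S(x - t) undefined)")
        out = np.exp(log_survival(params, x - t) - log_survival(params, t))
    return float(out) if np.ndim(out) == 0 else out
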