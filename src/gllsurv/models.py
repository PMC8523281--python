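"""Competitor and submodel families for the comparison battery.

Every family is addressed by name through the MODELS registry and exposes a
common surface (log-density, CDF, number of parameters, ML fit).  The
densities and CDFs are supplied by scipy.stats; the parameterizations follow
the rate convention of the two-parameter families (k = 1/scale) and the
shape/scale/location convention for the shifted three-parameter families.

Nested submodels of the GLL (Weibull, log-logistic, Burr XII, exponential,
standard log-logistic) are flagged so the likelihood-ratio battery can pair
them with the full model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import optimize, stats

from . import core
from .core import GLLParams
from .fit import FitResult, LifetimeSample, fit_gll

__all__ = ["ModelSpec", "MODELS", "density", "model_cdf", "fit"]


@dataclass(frozen=True)
class ModelSpec:
    name: str
    n_params: int
    param_names: tuple
    nested_in_gll: bool
    gll_df_diff: int | None  # df for the LRT against the full GLL
    logpdf: Callable  # (theta, x) -> array
    cdf: Callable
    shifted: bool = False  # last parameter is a location below min(data)


def _gll_logpdf(th, x):
    return core.logpdf(GLLParams(*th), x)


def _gll_cdf(th, x):
    return core.cdf(GLLParams(*th), x)


MODELS: dict[str, ModelSpec] = {}


def _register(spec: ModelSpec):
    MODELS[spec.name] = spec
    return spec


_register(ModelSpec("GLL", 3, ("alpha", "kappa", "eta"), True, 0, _gll_logpdf, _gll_cdf))
_register(ModelSpec(
    "W2", 2, ("alpha", "k"), True, 1,
    lambda th, x: stats.weibull_min.logpdf(x, th[0], scale=1 / th[1]),
    lambda th, x: stats.weibull_min.cdf(x, th[0], scale=1 / th[1]),
))
_register(ModelSpec(
    "LL2", 2, ("alpha", "k"), True, 1,
    lambda th, x: stats.fisk.logpdf(x, th[0], scale=1 / th[1]),
    lambda th, x: stats.fisk.cdf(x, th[0], scale=1 / th[1]),
))
_register(ModelSpec(
    "BurrXII", 2, ("alpha", "k"), True, 1,
    lambda th, x: stats.burr12.logpdf(x, th[0], th[1]),
    lambda th, x: stats.burr12.cdf(x, th[0], th[1]),
))
_register(ModelSpec(
    "Exp", 1, ("k",), True, 2,
    lambda th, x: stats.expon.logpdf(x, scale=1 / th[0]),
    lambda th, x: stats.expon.cdf(x, scale=1 / th[0]),
))
_register(ModelSpec(
    "StdLL", 1, ("alpha",), True, 2,
    lambda th, x: stats.fisk.logpdf(x, th[0]),
    lambda th, x: stats.fisk.cdf(x, th[0]),
))
_register(ModelSpec(
    "ExpW", 3, ("alpha", "k", "lam"), False, None,
    lambda th, x: stats.exponweib.logpdf(x, th[2], th[0], scale=1 / th[1]),
    lambda th, x: stats.exponweib.cdf(x, th[2], th[0], scale=1 / th[1]),
))
_register(ModelSpec(
    "LL3", 3, ("alpha", "scale", "mu"), False, None,
    lambda th, x: stats.fisk.logpdf(x, th[0], loc=th[2], scale=th[1]),
    lambda th, x: stats.fisk.cdf(x, th[0], loc=th[2], scale=th[1]),
    shifted=True,
))
_register(ModelSpec(
    "LN3", 3, ("sigma", "scale", "mu"), False, None,
    lambda th, x: stats.lognorm.logpdf(x, th[0], loc=th[2], scale=th[1]),
    lambda th, x: stats.lognorm.cdf(x, th[0], loc=th[2], scale=th[1]),
    shifted=True,
))
_register(ModelSpec(
    "W3", 3, ("alpha", "scale", "mu"), False, None,
    lambda th, x: stats.weibull_min.logpdf(x, th[0], loc=th[2], scale=th[1]),
    lambda th, x: stats.weibull_min.cdf(x, th[0], loc=th[2], scale=th[1]),
    shifted=True,
))
_register(ModelSpec(
    "G3", 3, ("shape", "scale", "mu"), False, None,
    lambda th, x: stats.gamma.logpdf(x, th[0], loc=th[2], scale=th[1]),
    lambda th, x: stats.gamma.cdf(x, th[0], loc=th[2], scale=th[1]),
    shifted=True,
))


def _get(spec) -> ModelSpec:
    if isinstance(spec, ModelSpec):
        return spec
    try:
        return MODELS[str(spec)]
    except KeyError:
        raise KeyError(f"unknown model {spec!r}; available: {sorted(MODELS)}") from None


def density(spec, theta, x) -> np.ndarray:
    """Density of a registered family at parameter vector `theta`."""
    spec = _get(spec)
    theta = np.asarray(theta, dtype=float)
    x = np.asarray(x, dtype=float)
    if spec.shifted:
        if np.any(theta[:-1] <= 0):
            raise ValueError("shape/scale parameters must be > 0")
        if np.any(x <= theta[-1]):
            raise ValueError("shifted families require x > mu")
    elif np.any(theta <= 0):
        raise ValueError("parameters must be > 0")
    with np.errstate(all="ignore"):
        return np.exp(spec.logpdf(theta, x))


def model_cdf(spec, theta, x) -> np.ndarray:
    spec = _get(spec)
    with np.errstate(all="ignore"):
        return spec.cdf(np.asarray(theta, dtype=float), np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# fitting


def _unpack(spec: ModelSpec, u: np.ndarray, xmin: float) -> np.ndarray:
    """Internal optimizer coordinates -> natural parameters."""
    if spec.shifted:
        th = np.empty(spec.n_params)
        th[:-1] = np.exp(u[:-1])
        th[-1] = xmin - 1e-8 - np.exp(u[-1])  # mu strictly below min(data)
        return th
    return np.exp(u)


def fit(spec, data: LifetimeSample, starts: int = 12, seed: int = 42) -> FitResult:
    """Maximum-likelihood fit of any registered family.

    Positive parameters are optimized on the log scale; a location is mapped
    onto (-inf, min(data)) through mu = min(x) - exp(u).  Multi-start
    Nelder-Mead with a BFGS polish; standard errors from a central-difference
    Hessian at the optimum when it is positive definite.
    """
    spec = _get(spec)
    if spec.name == "GLL":
        return fit_gll(data, starts=starts, seed=seed)

    x = data.sorted()
    xmin = float(x[0])
    rng = np.random.default_rng(seed)

    def nll(u):
        th = _unpack(spec, u, xmin)
        with np.errstate(all="ignore"):
            v = spec.logpdf(th, x)
        v = np.asarray(v)
        if not np.all(np.isfinite(v)):
            return np.inf
        return -v.sum()

    # data-driven base start: unit shapes, median scale, location just below xmin
    lmed = np.log(np.median(x))
    if spec.shifted:
        base = np.array([0.0, lmed, 0.0])
    elif spec.n_params == 1:
        base = np.array([-lmed]) if spec.name == "Exp" else np.array([0.0])
    else:
        base = np.zeros(spec.n_params)
        base[1] = -lmed  # rate ~ 1/median

    best = None
    for s in range(starts):
        u0 = base if s == 0 else base + rng.normal(0, 1.0, base.size)
        with np.errstate(all="ignore"):
            r = optimize.minimize(nll, u0, method="Nelder-Mead",
                                  options={"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-10})
            r2 = optimize.minimize(nll, r.x, method="BFGS", options={"maxiter": 300})
            if np.isfinite(r2.fun) and r2.fun < r.fun:
                r = optimize.minimize(nll, r2.x, method="Nelder-Mead",
                                      options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-11})
        if np.isfinite(r.fun) and (best is None or r.fun < best.fun):
            best = r
    if best is None:
        raise RuntimeError(f"all starts failed for model {spec.name}")

    theta = _unpack(spec, best.x, xmin)
    ll = -float(best.fun)

    vcov = se = None
    try:
        H = _numeric_hessian(lambda p: -spec.logpdf(p, x).sum(), theta)
        vc = np.linalg.inv((H + H.T) / 2)
        if np.all(np.diag(vc) > 0):
            vcov, se = vc, np.sqrt(np.diag(vc))
    except (np.linalg.LinAlgError, FloatingPointError, ValueError):
        warnings.warn(f"no covariance for {spec.name}: Hessian not invertible")

    return FitResult(
        params=None, loglik=ll, vcov=vcov, se=se, ci=None, level=0.95,
        converged=bool(np.isfinite(ll)), n_starts=starts, model=spec.name,
        estimates=theta,
    )


def _numeric_hessian(f, th: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    m = th.size
    h = rel_step * np.maximum(np.abs(th), 1e-3)
    H = np.empty((m, m))
    with np.errstate(all="ignore"):
        for i in range(m):
            for j in range(m):
                pi = np.zeros(m)
                pj = np.zeros(m)
                pi[i] = h[i]
                pj[j] = h[j]
                H[i, j] = (
                    f(th + pi + pj) - f(th + pi - pj) - f(th - pi + pj) + f(th - pi - pj)
                ) / (4 * h[i] * h[j])
    return H
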