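"""Model comparison: information criteria, goodness of fit, LRTs, TTT, descriptives."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import models
from .fit import FitResult, LifetimeSample

__all__ = [
    "GofReport",
    "LRTResult",
    "information_criteria",
    "anderson_darling",
    "cramer_von_mises",
    "ks_test",
    "lrt",
    "lrt_battery",
    "ttt_transform",
    "classify_hazard_shape",
    "describe",
    "gof_report",
    "compare_models",
]

# the five nested-submodel hypotheses tested against the full GLL
LRT_BATTERY = ("W2", "LL2", "BurrXII", "Exp", "StdLL")


@dataclass(frozen=True)
class GofReport:
    model: str
    n_params: int
    loglik: float
    aic: float
    bic: float
    caic: float
    hqic: float
    ad_stat: float
    cvm_stat: float
    ks_stat: float
    ks_pvalue: float


@dataclass(frozen=True)
class LRTResult:
    null_model: str
    alt_model: str
    statistic: float
    df: int
    pvalue: float


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float, float, float]:
    """(AIC, BIC, CAIC, HQIC) for a model with k parameters on n observations."""
    aic = 2 * k - 2 * loglik
    bic = k * np.log(n) - 2 * loglik
    caic = 2 * n * k / (n - k - 1) - 2 * loglik
    hqic = 2 * k * np.log(np.log(n)) - 2 * loglik
    return aic, bic, caic, hqic


def _clamp(g: np.ndarray) -> np.ndarray:
    eps = np.finfo(float).eps
    if np.any(g <= 0) or np.any(g >= 1):
        warnings.warn("fitted CDF values at 0 or 1 clamped to machine bounds")
    return np.clip(g, eps, 1 - eps)


def anderson_darling(cdf_values) -> float:
    """A* = -n - (1/n) sum (2i-1) [ln G(x_(i)) + ln(1 - G(x_(n-i+1)))]."""
    g = _clamp(np.sort(np.asarray(cdf_values, dtype=float)))
    n = g.size
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(g) + np.log1p(-g[::-1]))))


def cramer_von_mises(cdf_values) -> float:
    """W* = 1/(12n) + sum [G(x_(i)) - (2i-1)/(2n)]^2."""
    g = _clamp(np.sort(np.asarray(cdf_values, dtype=float)))
    n = g.size
    i = np.arange(1, n + 1)
    return float(1 / (12 * n) + np.sum((g - (2 * i - 1) / (2 * n)) ** 2))


def ks_test(data: LifetimeSample, cdf) -> tuple[float, float]:
    """Kolmogorov-Smirnov sup distance of the fitted CDF, asymptotic p-value."""
    x = data.sorted()
    n = data.n
    g = np.asarray(cdf(x), dtype=float)
    i = np.arange(1, n + 1)
    d = float(max(np.max(i / n - g), np.max(g - (i - 1) / n)))
    p = float(stats.kstwobign.sf(np.sqrt(n) * d))
    return d, min(max(p, 0.0), 1.0)


def lrt(null_fit, alt_fit, df: int) -> LRTResult:
    """-2 log likelihood ratio, clipped at 0, against chi-square(df)."""
    if df < 1:
        raise ValueError("df must be a positive integer")
    stat = max(0.0, -2 * (null_fit.loglik - alt_fit.loglik))
    p = float(stats.chi2.sf(stat, df))
    return LRTResult(
        null_model=getattr(null_fit, "model", "null"),
        alt_model=getattr(alt_fit, "model", "alt"),
        statistic=float(stat), df=int(df), pvalue=p,
    )


def lrt_battery(data: LifetimeSample, gll_fit: FitResult | None = None,
                seed: int = 42) -> list[LRTResult]:
    """The five nested-submodel tests against the full GLL."""
    alt = gll_fit if gll_fit is not None else models.fit("GLL", data, seed=seed)
    out = []
    for name in LRT_BATTERY:
        spec = models.MODELS[name]
        null = models.fit(name, data, seed=seed)
        out.append(lrt(null, alt, df=spec.gll_df_diff))
    return out


def ttt_transform(data: LifetimeSample) -> np.ndarray:
    """Scaled total-time-on-test curve.

    Returns an (n+1, 2) array of points (r/n, G(r/n)) with
    G(r/n) = [sum_{i<=r} x_(i) + (n-r) x_(r)] / sum_i x_i, G(0) = 0, G(1) = 1.
    """
    x = data.sorted()
    n = data.n
    cs = np.cumsum(x)
    r = np.arange(1, n + 1)
    g = (cs + (n - r) * x) / cs[-1]
    return np.column_stack([np.concatenate([[0.0], r / n]), np.concatenate([[0.0], g])])


def classify_hazard_shape(ttt: np.ndarray, tol: float | None = None) -> str:
    """Hazard-shape triage from the scaled TTT curve.

    A concave curve (above the diagonal) signals an increasing hazard, a
    convex one (below) a decreasing hazard, concave-then-convex a unimodal
    hazard and convex-then-concave a bathtub.  The verdict is read off the
    locations and magnitudes of the extreme deviations G - r/n: excursions
    below `tol` (default 0.5/sqrt(n), the noise scale of the empirical
    transform) are ignored, and a curve with no significant excursion is
    'constant'.
    """
    rn, g = ttt[:, 0], ttt[:, 1]
    dev = g - rn
    n = rn.size
    if tol is None:
        tol = 0.5 / np.sqrt(n)
    i_up, i_dn = int(np.argmax(dev)), int(np.argmin(dev))
    has_up = dev[i_up] > tol  # a significant concave (above-diagonal) excursion
    has_dn = -dev[i_dn] > tol
    if not has_up and not has_dn:
        return "constant"
    if has_up and not has_dn:
        return "increasing"
    if has_dn and not has_up:
        return "decreasing"
    return "unimodal" if i_up < i_dn else "bathtub"


def describe(data: LifetimeSample, mode_bins: int = 10) -> dict:
    """Descriptive statistics of the sample.

    Variance uses the n-1 divisor; skewness and kurtosis use the biased
    moment estimators g1 = m3/m2^(3/2) and g2 = m4/m2^2 - 3 (excess).  Two
    modes are reported: the most frequent exact value ('mode_raw', ties ->
    smallest) and the midpoint of the fullest histogram bin ('mode_binned').
    """
    x = data.times
    m = x - x.mean()
    m2, m3, m4 = (m**2).mean(), (m**3).mean(), (m**4).mean()
    skew = m3 / m2**1.5 if m2 > 0 else 0.0
    kurt = m4 / m2**2 - 3.0 if m2 > 0 else 0.0
    vals, counts = np.unique(x, return_counts=True)
    hist, edges = np.histogram(x, bins=mode_bins)
    b = int(np.argmax(hist))
    return {
        "n": data.n,
        "mean": float(x.mean()),
        "median": float(np.median(x)),
        "mode_raw": float(vals[np.argmax(counts)]),
        "mode_binned": float((edges[b] + edges[b + 1]) / 2),
        "variance": float(x.var(ddof=1)) if data.n > 1 else 0.0,
        "skewness": float(skew),
        "kurtosis": float(kurt),
        "min": float(x.min()),
        "max": float(x.max()),
    }


def gof_report(name: str, fitres: FitResult, data: LifetimeSample) -> GofReport:
    """Information criteria and goodness-of-fit statistics for one fitted model."""
    spec = models.MODELS[name]
    g = models.model_cdf(spec, fitres.estimates, data.sorted())
    aic, bic, caic, hqic = information_criteria(fitres.loglik, spec.n_params, data.n)
    d, p = ks_test(data, lambda t: models.model_cdf(spec, fitres.estimates, t))
    return GofReport(
        model=name, n_params=spec.n_params, loglik=fitres.loglik,
        aic=aic, bic=bic, caic=caic, hqic=hqic,
        ad_stat=anderson_darling(g), cvm_stat=cramer_von_mises(g),
        ks_stat=d, ks_pvalue=p,
    )


def compare_models(data: LifetimeSample, names=None, seed: int = 42) -> pd.DataFrame:
    """Fit a battery of families and tabulate ICs and GoF, sorted by AIC."""
    names = list(names) if names is not None else list(models.MODELS)
    rows = []
    fits = {}
    for name in names:
        fr = models.fit(name, data, seed=seed)
        fits[name] = fr
        rows.append(gof_report(name, fr, data).__dict__)
    df = pd.DataFrame(rows).set_index("model").sort_values("aic")
    df.attrs["fits"] = fits
    return df
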