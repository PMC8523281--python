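"""MCMC convergence diagnostics.

All diagnostics are pure functions of a draw vector/matrix and are reusable
for any chain, not just the GLL posterior: Geweke's z, autocorrelation,
Heidelberger-Welch stationarity/halfwidth, Raftery-Lewis run-length, the
Gelman-Rubin potential scale reduction factor, and the running (ergodic)
mean.  Spectral variances use a Tukey-Hanning lag window with bandwidth
floor(sqrt(n)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from statsmodels.tsa.stattools import acf as _sm_acf

__all__ = [
    "geweke", "autocorr", "heidelberger_welch", "raftery_lewis",
    "gelman_rubin", "ergodic_mean", "spectral_variance",
    "DiagnosticsReport", "diagnostics_report",
]


def spectral_variance(x: np.ndarray) -> float:
    """Estimate of S(0)/n, the large-sample variance of the sample mean.

    Tukey-Hanning lag window w_l = (1 + cos(pi l / L)) / 2, L = floor(sqrt(n)).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return float("nan")
    L = max(1, int(np.sqrt(n)))
    d = x - x.mean()
    g0 = (d @ d) / n
    s0 = g0
    for lag in range(1, min(L, n - 1) + 1):
        g = (d[:-lag] @ d[lag:]) / n
        s0 += 2 * 0.5 * (1 + np.cos(np.pi * lag / L)) * g
    return float(max(s0, 0.0) / n)


def geweke(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke z-score comparing the mean of the first and last chain fractions."""
    x = np.asarray(chain, dtype=float)
    n = x.size
    a = x[: int(first * n)]
    b = x[n - int(last * n):]
    va, vb = spectral_variance(a), spectral_variance(b)
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))


def autocorr(chain: np.ndarray, max_lag: int = 50) -> np.ndarray:
    """Biased-normalized autocorrelation function at lags 0..max_lag."""
    x = np.asarray(chain, dtype=float)
    return _sm_acf(x, nlags=min(max_lag, x.size - 1), adjusted=False, fft=True)


def _pcramer(q: float) -> float:
    """CDF of the asymptotic Cramer-von Mises distribution (4-term series)."""
    if q <= 0:
        return 0.0
    if q >= 2.0:  # CDF is 1 - 1.3e-5 at q = 2; the series loses accuracy beyond
        return 1.0
    total = 0.0
    for k in range(4):
        z = special.gamma(k + 0.5) * np.sqrt(4 * k + 1) / (
            special.gamma(k + 1.0) * np.pi**1.5 * np.sqrt(q))
        u = (4 * k + 1) ** 2 / (16 * q)
        if u < 700:
            total += z * np.exp(-u) * special.kv(0.25, u)
    return float(min(max(total, 0.0), 1.0))


def heidelberger_welch(chain: np.ndarray, eps: float = 0.1, alpha: float = 0.05) -> dict:
    """Heidelberger-Welch stationarity and halfwidth tests.

    The stationarity stage computes the Cramer-von Mises statistic of the
    standardized Brownian bridge of cumulative sums, discarding successive
    initial 10% segments until it is non-significant at `alpha` (at most 50%
    discarded).  The halfwidth stage passes when the 95% interval halfwidth
    of the retained mean is below `eps` times |mean|.
    """
    x = np.asarray(chain, dtype=float)
    n0 = x.size
    stat_pass = False
    pvalue = 0.0
    start = 0
    for frac in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        start = int(frac * n0)
        y = x[start:]
        n = y.size
        s0n = spectral_variance(y[n // 2:]) * (n - n // 2)  # S(0) from latter half
        if not np.isfinite(s0n) or s0n <= 0:
            break
        csum = np.cumsum(y)
        t = np.arange(1, n + 1)
        bridge = (csum - t * y.mean()) / np.sqrt(n * s0n)
        cvm = float(np.mean(bridge**2))
        pvalue = 1.0 - _pcramer(cvm)
        if pvalue > alpha:
            stat_pass = True
            break
    retained = x[start:] if stat_pass else x
    se = np.sqrt(spectral_variance(retained))
    halfwidth = stats.norm.ppf(0.975) * se
    hw_pass = bool(stat_pass and halfwidth < eps * abs(retained.mean()))
    return {
        "stationarity": stat_pass,
        "stationarity_pvalue": pvalue,
        "n_discarded": start if stat_pass else 0,
        "mean": float(retained.mean()),
        "halfwidth": float(halfwidth),
        "halfwidth_test": hw_pass,
    }


def raftery_lewis(chain: np.ndarray, q: float = 0.025, r: float = 0.005,
                  s: float = 0.95, eps: float = 0.001) -> dict:
    """Raftery-Lewis run-length diagnostic for estimating the q-quantile to
    accuracy +/- r with probability s.

    Dichotomizes the chain at its empirical q-quantile, thins the binary
    chain until first-order Markov dependence is preferred over second-order
    (BIC), then derives burn-in, required sample size and the dependence
    factor from the fitted two-state transition matrix.
    """
    x = np.asarray(chain, dtype=float)
    n = x.size
    phi = stats.norm.ppf(0.5 * (1 + s))
    nmin = int(np.ceil(q * (1 - q) * (phi / r) ** 2))
    if n < nmin / 10:
        raise ValueError(f"chain too short for these settings (need ~{nmin})")
    u = (x <= np.quantile(x, q)).astype(int)

    kthin = 1
    while True:
        z = u[::kthin]
        if z.size < 3:
            break
        # compare second-order vs first-order Markov via BIC on triple counts
        trip = np.zeros((2, 2, 2))
        for a, b, c in zip(z[:-2], z[1:-1], z[2:]):
            trip[a, b, c] += 1
        g2 = 0.0
        for a in range(2):
            for b in range(2):
                for c in range(2):
                    o = trip[a, b, c]
                    if o == 0:
                        continue
                    e = trip[a, b, :].sum() * trip[:, b, c].sum() / max(trip[:, b, :].sum(), 1)
                    if e > 0:
                        g2 += 2 * o * np.log(o / e)
        bic = g2 - np.log(max(z.size - 2, 1)) * 2
        if bic < 0:
            break
        kthin += 1
        if kthin > n // 50:
            break

    z = u[::kthin]
    pairs = np.zeros((2, 2))
    for a, b in zip(z[:-1], z[1:]):
        pairs[a, b] += 1
    row = pairs.sum(axis=1)
    alpha_p = pairs[0, 1] / row[0] if row[0] else 0.5  # P(0 -> 1)
    beta_p = pairs[1, 0] / row[1] if row[1] else 0.5  # P(1 -> 0)
    ab = alpha_p + beta_p
    if ab <= 0 or ab >= 2 or alpha_p == 0 or beta_p == 0:
        burn = kthin
        nreq = nmin * kthin
    else:
        lam = 1 - ab
        burn = int(np.ceil(np.log(eps * ab / max(alpha_p, beta_p)) / np.log(abs(lam)))) * kthin
        nreq = int(np.ceil((2 - ab) * alpha_p * beta_p / ab**3 * (phi / r) ** 2)) * kthin
    total = burn + nreq
    return {
        "thin": kthin,
        "burn_in": burn,
        "required_n": nreq,
        "total_n": total,
        "nmin": nmin,
        "dependence_factor": total / nmin,
    }


def gelman_rubin(chains: np.ndarray) -> float:
    """Classic potential scale reduction factor for m >= 2 chains of length n.

    psrf = sqrt(((n-1)/n W + B/n) / W); equals sqrt((n-1)/n) ~ 1 when the
    chains are identical.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("need a (m, n) array with m >= 2 chains")
    m, n = c.shape
    w = c.var(axis=1, ddof=1).mean()
    b_over_n = c.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    return float(np.sqrt(((n - 1) / n * w + b_over_n) / w))


def ergodic_mean(chain: np.ndarray) -> np.ndarray:
    """Running mean of the chain; the last element is the chain mean."""
    x = np.asarray(chain, dtype=float)
    return np.cumsum(x) / np.arange(1, x.size + 1)


@dataclass
class DiagnosticsReport:
    geweke_z: np.ndarray  # chains x params
    psrf: np.ndarray  # params
    hw: list  # per chain: list of per-param dicts
    rl: list  # per chain: list of per-param dicts
    acf_lag1: np.ndarray  # chains x params
    param_names: tuple

    def all_converged(self, z_bound: float = 2.0, psrf_bound: float = 1.1) -> bool:
        hw_ok = all(d["stationarity"] and d["halfwidth_test"]
                    for per_chain in self.hw for d in per_chain)
        return bool(np.all(np.abs(self.geweke_z) < z_bound)
                    and np.all(self.psrf < psrf_bound) and hw_ok)


def diagnostics_report(draws: np.ndarray, param_names=("alpha", "kappa", "eta")) -> DiagnosticsReport:
    """Run the full battery on a chains x iterations x params draw array."""
    d = np.asarray(draws, dtype=float)
    if d.ndim == 2:
        d = d[None, ...]
    n_chains, _, n_par = d.shape
    gz = np.array([[geweke(d[c, :, j]) for j in range(n_par)] for c in range(n_chains)])
    a1 = np.array([[autocorr(d[c, :, j], 1)[1] for j in range(n_par)] for c in range(n_chains)])
    hw = [[heidelberger_welch(d[c, :, j]) for j in range(n_par)] for c in range(n_chains)]
    rl = [[raftery_lewis(d[c, :, j]) for j in range(n_par)] for c in range(n_chains)]
    if n_chains >= 2:
        psrf = np.array([gelman_rubin(d[:, :, j]) for j in range(n_par)])
    else:
        psrf = np.full(n_par, np.nan)
    return DiagnosticsReport(geweke_z=gz, psrf=psrf, hw=hw, rl=rl, acf_lag1=a1,
                             param_names=tuple(param_names))
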