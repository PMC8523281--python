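"""Monte Carlo performance study of the GLL maximum-likelihood estimators.

For each sample size n, `replicates` datasets are drawn by inverse-CDF
transform from the true parameters, each is fitted by maximum likelihood,
and the average bias AB = mean(theta_hat - theta), MSE and RMSE = sqrt(MSE)
are aggregated per parameter.  Aggregation is streamed so the full study
does not hold all replicate estimates in memory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core, fit as _fit
from .core import GLLParams
from .fit import LifetimeSample

__all__ = ["SimScenario", "SimResult", "run_study", "SET_I", "SET_II", "DEFAULT_SIZES"]

SET_I = GLLParams(alpha=0.9, kappa=0.5, eta=2.5)
SET_II = GLLParams(alpha=0.8, kappa=0.4, eta=2.0)
DEFAULT_SIZES = (50, 100, 300, 600, 900, 1200, 1500)
PARAM_NAMES = ("alpha", "kappa", "eta")


@dataclass(frozen=True)
class SimScenario:
    truth: GLLParams
    sample_sizes: tuple = DEFAULT_SIZES
    replicates: int = 1500
    seed: int = 0
    starts: int = 3  # optimizer starts per replicate fit

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(n < 10 for n in self.sample_sizes):
            raise ValueError("sample sizes must be >= 10")


@dataclass
class SimResult:
    scenario: SimScenario
    table: pd.DataFrame  # index (parameter, n); columns mean_mle, ab, mse, rmse
    n_failed: dict = field(default_factory=dict)
    unreliable: list = field(default_factory=list)
    draws: np.ndarray | None = None


def run_study(scenario: SimScenario, keep_draws: bool = False) -> SimResult:
    """Run the full bias/MSE/RMSE study for one true-parameter scenario."""
    truth = scenario.truth.as_array()
    ss = np.random.SeedSequence(scenario.seed)
    rows = []
    n_failed = {}
    unreliable = []
    all_draws = [] if keep_draws else None

    for n, child in zip(scenario.sample_sizes, ss.spawn(len(scenario.sample_sizes))):
        rng = np.random.default_rng(child)
        count = 0
        s1 = np.zeros(3)
        s2 = np.zeros(3)
        sdiff = np.zeros(3)
        sdiff2 = np.zeros(3)
        failed = 0
        for rep in range(scenario.replicates):
            x = core.random_sample(scenario.truth, n, rng)
            fit_seed = int(rng.integers(2**31 - 1))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fr = _fit.fit_gll(LifetimeSample(x), starts=scenario.starts,
                                      seed=fit_seed, compute_vcov=False)
            except (RuntimeError, FloatingPointError):
                failed += 1
                continue
            est = fr.params.as_array()
            if not fr.converged or not np.all(np.isfinite(est)):
                failed += 1
                continue
            d = est - truth
            count += 1
            s1 += est
            s2 += est**2
            sdiff += d
            sdiff2 += d**2
            if keep_draws:
                all_draws.append(np.concatenate([[n], est]))
        n_failed[n] = failed
        if failed > 0.05 * scenario.replicates:
            unreliable.append(n)
        if count == 0:
            continue
        mean_mle = s1 / count
        ab = sdiff / count
        mse = sdiff2 / count
        for j, pname in enumerate(PARAM_NAMES):
            rows.append({
                "parameter": pname, "n": n, "mean_mle": mean_mle[j],
                "ab": ab[j], "mse": mse[j], "rmse": np.sqrt(mse[j]),
                "n_ok": count,
            })

    table = pd.DataFrame(rows).set_index(["parameter", "n"])
    return SimResult(
        scenario=scenario, table=table, n_failed=n_failed, unreliable=unreliable,
        draws=np.array(all_draws) if keep_draws else None,
    )
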