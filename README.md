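# gllsurv

Parametric survival analysis with the **generalized log-logistic (GLL)
distribution** — a three-parameter lifetime model whose hazard

```
h(x) = α k (kx)^(α−1) / (1 + (ηx)^α),        α, k, η > 0
```

combines Weibull-like early behaviour with a log-logistic tail.  Writing
c = (k/η)^α, the survival function is S(x) = (1 + (ηx)^α)^(−c).  The hazard
is non-increasing for α ≤ 1 and unimodal with mode (α−1)^(1/α)/η for α > 1,
and the family nests the models survival analysts reach for first:

| submodel | constraint |
|---|---|
| log-logistic | k = η |
| standard log-logistic | k = η = 1 |
| Burr XII | η = k·λ^(−1/α), λ > 0 |
| Weibull | η^α → 0 |
| exponential | η^α → 0, α = 1 |

The package is aimed at biostatisticians and reliability analysts fitting
complete (uncensored) samples of positive lifetimes.  It provides:

- **Closed-form properties** (`gllsurv.core`): pdf, CDF, survival, hazard,
  reversed hazard, cumulative hazard, quantiles, inverse-CDF random
  deviates, raw/negative moments with their existence conditions
  (E[T^r] is finite iff α·c > r), quantile-based Galton/Moors shape
  measures, residual life.  Everything is evaluated in log space so that
  c ~ 10⁵ does not overflow.
- **Maximum likelihood** (`gllsurv.fit`): multi-start quasi-Newton on
  log-parameters with the analytic score, observed-information covariance
  and Wald intervals.
- **Model comparison** (`gllsurv.models`, `gllsurv.selection`): a registry
  of nine competitor families (Weibull, log-logistic, Burr XII,
  exponentiated Weibull, shifted log-logistic/log-normal/Weibull/gamma, …),
  AIC/BIC/CAIC/HQIC, Anderson–Darling, Cramér–von Mises,
  Kolmogorov–Smirnov, nested likelihood-ratio tests, the scaled
  total-time-on-test (TTT) transform with hazard-shape triage.
- **Monte Carlo estimator studies** (`gllsurv.simulation`): bias/MSE/RMSE
  of the MLEs across sample sizes.
- **Bayesian inference** (`gllsurv.bayes`, `gllsurv.diagnostics`):
  Metropolis-within-Gibbs under independent gamma priors, posterior
  summaries with equal-tail and HPD intervals, and a convergence battery
  (Geweke, autocorrelation, Heidelberger–Welch, Raftery–Lewis,
  Gelman–Rubin, ergodic means).

A 128-patient bladder-cancer remission-time dataset (months) ships as the
fixture `"bladder128"`.

## Worked example

```sh
$ gllsurv fit --data bladder128
model: GLL
n: 128
estimates:
  alpha: 1.4266516745071822
  kappa: 0.1383306769667923
  eta: 0.08297998550548667
se:
  alpha: 0.17775514850078636
  kappa: 0.017583961642151966
  eta: 0.03993712056580088
loglik: -409.74229638138985
converged: true
```

The fitted shape exponent α̂ ≈ 1.43 > 1 says the remission hazard rises to
a peak and then declines — consistent with the TTT curve
(`gllsurv ttt --data bladder128` classifies it as `unimodal`).  κ̂ and η̂
are rates per month; their gap (κ̂ ≠ η̂) is what the log-logistic submodel
cannot express, and the likelihood-ratio test of that restriction gives
3.45 on 1 df.  Comparing families:

```sh
$ gllsurv compare --data bladder128 --models GLL,LN3,LL2,W2 --format tsv
model  n_params  loglik    aic      bic      caic     hqic
GLL    3         -409.742  825.485  834.041  825.678  828.961
LN3    3         -410.354  826.709  835.265  826.902  830.185
LL2    2         -411.466  826.931  832.635  827.027  829.249
W2     2         -414.080  832.159  837.863  832.255  834.477
```

The GLL has the best log-likelihood and the lowest AIC/CAIC/HQIC (the
two-parameter log-logistic edges it on BIC, which penalizes the third
parameter by ln n).  Its goodness-of-fit statistics on this data are
A\* = 0.120, W\* = 0.017, K-S D = 0.033 (p ≈ 0.999).

Bayesian estimation with unit-rate gamma priors:

```sh
$ gllsurv bayes --data bladder128 --diagnostics
```

runs three 50 000-iteration chains (5 000 burn-in, thinned by 5) and
reports, e.g., a posterior mean of α of about 1.44 with 95% credible
interval ≈ (1.13, 1.82), plus the convergence battery (all Geweke |z| < 2,
Heidelberger–Welch passed, PSRF ≈ 1.00).

The same operations are available as library calls (`fit_gll`,
`compare_models`, `lrt_battery`, `run_study`, `sample_posterior`,
`summarize`, `diagnostics_report`).

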