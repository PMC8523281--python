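# Methods

## Model

The generalized log-logistic (GLL) distribution for a positive lifetime T
has hazard h(x) = αk(kx)^(α−1)/(1 + (ηx)^α) with shape α > 0 and rates
k, η > 0 (units 1/time).  With c = (k/η)^α the survival function is
S(x) = (1 + (ηx)^α)^(−c) and the density f = h·S.  The tail decays like
x^(−1−αc), so E[T^r] exists iff αc > r; the closed forms are

- E[T^r]  = Γ(r/α + 1) Γ(c − r/α) / (η^r Γ(c)),
- E[T^−r] = η^r Γ(1 − r/α) Γ(c + r/α) / Γ(c)  (requires r < α),

and the quantile function is Q(p) = ((1/(1−p))^(1/c) − 1)^(1/α)/η.
Hazard shape: non-increasing for α ≤ 1, unimodal with mode (α−1)^(1/α)/η
for α > 1.  Reparameterizations in the source material that differ only
typographically (a λ used interchangeably with η, a β for α) are collapsed
onto the single triple (α, k, η); formulas whose printed versions are
OCR-damaged (reversed hazard, random deviate, negative moment, cumulants,
score) are derived from the defining identities and certified against
quadrature, simulation or finite-difference oracles in the test suite.

Scope: complete (uncensored) samples only; no covariates; no entropy or
order-statistic machinery.

## Numerical choices

- All powers go through log space: c = exp(α(log k − log η)),
  log(1 + (ηx)^α) = logaddexp(0, α log(ηx)), gamma ratios through
  log-gamma differences.  This keeps triples with c ~ 10⁵ (or 10⁻⁵)
  finite.  Quantiles are also assembled in log space; a triple whose true
  quantile exceeds double range (~1e308) returns inf.
- At x = 0 the density and hazard return their analytic limits (0 for
  α > 1, k for α = 1, +inf for α < 1).
- Moment requests outside the existence region raise
  `MomentNotDefinedError` instead of returning gamma-function poles.

## Maximum likelihood

The log-likelihood ℓ = n log α + nα log k + (α−1)Σlog xᵢ −
(c+1)Σlog(1+(ηxᵢ)^α) is maximized over (log α, log k, log η) by
multi-start BFGS with the analytic score, followed by a Nelder–Mead
polish; convergence is certified by the relative score sup-norm (< 1e−4).
Default 10 starts: one moment-matching point (α from the Weibull relation
Var(log T) = π²/(6α²), k = η = 1/median) plus log-normal perturbations
(σ = 0.7).  The covariance is the inverse observed information, computed
by central finite differences (relative step 1e−4) and symmetrized; Wald
intervals use the normal quantile at the requested level (default 95%).

On the bladder-cancer fixture the converged optimum is
(α̂, k̂, η̂) = (1.4267, 0.1383, 0.0830) with ℓ = −409.742.  Published
analyses of this dataset print the nearby point (1.410, 0.134, 0.077) with
ℓ = −409.78; the gradient there is not zero, while the published
covariance matrix and likelihood-ratio statistics match the converged
optimum, so the package reports the converged values.  The same effect
explains small gaps in derived quantities (e.g. A* = 0.120 at the optimum
vs a published 0.128, and an AIC of 825.48 vs 825.56).

Competitor families reuse scipy.stats distributions behind a common
registry.  Two-parameter families use the rate convention (scale = 1/k);
shifted three-parameter families optimize the location through
μ = min(x) − exp(u), keeping μ strictly below the sample minimum (their
likelihood can be unbounded as μ → min(x) for some shapes).  Note that
the log-logistic fit is often published in the AFT parameterization
(1/shape, log scale); the registry stores shape/rate.

## Likelihood-ratio battery

The five nested reductions (Weibull, log-logistic, Burr XII, exponential,
standard log-logistic) are tested with −2 log Λ against χ² with df equal
to the parameter difference.  The Weibull reduction (η^α → 0) is a
boundary hypothesis for which the χ² reference is anticonservative; it is
used anyway, as is conventional, with this caveat.  On the fixture the
statistics are 8.68 (W2), 3.45 (LL2), 87.46 (Burr XII), 9.18 (Exp),
190.14 (StdLL); a published LL2 value of 10.8 is irreconcilable with the
published log-likelihoods (−411.47 vs −409.78 imply ≈ 3.4) and the
recomputed value is reported.

## Goodness of fit and descriptives

A* and W* use the standard order-statistic forms on the fitted CDF values
(clamped away from 0/1 with a warning); K-S p-values come from the
asymptotic Kolmogorov distribution at √n·D.  The TTT curve is the scaled
total time on test G(r/n) = [Σ_{i≤r} x₍ᵢ₎ + (n−r)x₍ᵣ₎]/Σx₍ᵢ₎; shape
triage reads the locations of the extreme deviations from the diagonal,
ignoring excursions below 0.5/√n — a screening heuristic, not a test, and
deliberately insensitive at large n where tiny fluctuations are
significant but practically irrelevant.  Sample skewness and kurtosis use
the biased moment estimators with excess kurtosis (g₁, g₂), the
convention under which the fixture reproduces its published descriptives
(3.286, 15.481).  Both a raw-repeat mode and a histogram-bin mode are
reported, as heavily tied continuous data make "the" mode convention-
dependent.

## Monte Carlo study

For each sample size, `replicates` datasets are drawn by inverse-CDF
transform, fitted with 3 optimizer starts (no covariance), and aggregated
streamingly into AB = mean(θ̂−θ), MSE and RMSE.  Scenario presets:
set I (0.9, 0.5, 2.5) and set II (0.8, 0.4, 2.0), sizes 50–1500,
1500 replicates.  Note both scenarios have αc < 1: the data are extremely
heavy-tailed (no finite mean), which is why small-n RMSEs are huge and why
no trimming is applied — none is part of the study design.  Failed or
non-converged fits are dropped and counted; a cell with > 5% failures is
flagged unreliable.  The acceptance script and test suite run the n = 1500
cell with 300 replicates and the size trend with 200 (the full 1500 is a
CLI/API call away); at 300 replicates the Monte Carlo error of RMSE(α̂) is
about 0.002, well inside the bands asserted.

## Bayesian inference

Independent Gamma(aᵢ, bᵢ) priors (default all shape = rate = 1) on
(α, k, η).  The full conditionals are nonstandard, so sampling is
Metropolis-within-Gibbs: each component in turn gets a Gaussian
random-walk proposal on the log scale (log-normal Jacobian included),
cycling α → k → η.  Proposal scales adapt by Robbins–Monro every 100
proposals during burn-in, targeting 0.44 acceptance (the one-dimensional
random-walk optimum), then freeze.  Defaults mirror the study design:
3 chains × 50 000 iterations, 5 000 burn-in, thin 5; chain 1 starts at
the MLE, later chains at the MLE × 0.5, 2, … component-wise.

Summaries per chain and pooled: mean, SD, naive SE = SD/√n, time-series
SE by batch means (50 batches; also reported as "MC error" — the source
material does not define a distinction), five-point summary, 2.5/97.5
percentiles, histogram mode (512 bins), skewness/kurtosis (same
convention as the descriptives), equal-tail and Chen–Shao HPD intervals.

Diagnostics: Geweke z (first 10% vs last 50%, Tukey–Hanning spectral
variance with bandwidth ⌊√n⌋), ACF, Heidelberger–Welch (Cramér–von Mises
stationarity via the Csörgő–Faraway series with iterative 10% discards,
then the 1.96·SE/|mean| < 0.1 halfwidth check), Raftery–Lewis
(q = 0.025, accuracy r = 0.005, s = 0.95 — the r that reproduces the
published minimum sample size ≈ 3746; a stated ±0.0005 would imply
≈ 374 000 and contradicts the published totals), and the classic
Gelman–Rubin PSRF.  All diagnostics are pure functions of draw arrays and
reusable for any chain.

Known limitation: component-wise random-walk updates mix slowly under the
strong α–η posterior correlation (~0.83 on the fixture).  Raftery–Lewis
dependence factors are 3–5 here, where a slice-sampling implementation
reports ≈ 1.1; posterior means, intervals and the convergence verdicts are
unaffected, but users wanting near-independent draws should thin further.

## Synthetic data and what the tests show

The generator is the exact inverse-CDF transform of the model itself, so
simulation tests certify internal consistency (estimator calibration,
sampler correctness against a quadrature reference posterior, diagnostic
null behaviour on AR(1)/iid chains) — they do not probe robustness to
model misspecification, censoring, covariates or measurement rounding,
all of which real remission-time data have.  The bladder-cancer fixture
is the only real-data anchor; its reproduction (fit, GoF battery,
rankings, posterior summaries) is the package's end-to-end evidence.

## Determinism

Every stochastic entry point takes a seed; child streams are spawned via
`numpy.random.SeedSequence`, so the Monte Carlo study, the sampler and the
acceptance script are bit-reproducible for a given seed and version.
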