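# Methods

This note records the statistical content of `nphtrial`: the estimators and
tests as implemented, the generative models behind the simulator, the
calibration of effect sizes, and the numerical and design choices that were
genuinely open.

## Counting-process backbone

All non-parametric methods reduce the trial to the ordered unique observed
event times `t_1 < … < t_k` with per-arm risk sets `Y_i(t_j)` and event
counts `dN_i(t_j)`. Conditionally on the margins at `t_j`, the control
event count is treated as hypergeometric, giving
`e₀ = dN·Y₀/Y` and `v = dN·(Y₀/Y)(1−Y₀/Y)(Y−dN)/(Y−1)` (set to 0 when
`Y = 1`); the `(Y−dN)/(Y−1)` factor is the tie correction. Ties between an
event and a censoring at the same time are resolved event-first, so the
censored subject is still in that event's risk set.

Two survival estimators coexist deliberately: the Nelson–Aalen–Breslow
(NAB) exponentiated cumulative hazard `exp(−Σ dN/Y)` is used everywhere an
estimand is computed and for Fleming–Harrington weights, while the
Kaplan–Meier product limit is used only inside the modestly weighted test's
weights. They agree to first order (`exp(−x) ≥ 1−x` makes NAB ≥ KM
pointwise) but are not interchanged, since the weight functions are defined
against specific estimators.

Time is handled in months throughout, with 1 month = 365.25/12 days;
conversion to days happens only at reporting (e.g. the 123-day calibration
target).

## Tests

The weighted log-rank statistic is
`z = Σ_j w_j (dN₀(t_j) − e₀(t_j)) / √(Σ_j w_j² v_j)`, oriented so that
positive z (excess control events) means treatment benefit; one-sided p
from the standard-normal upper tail. Weight families:

- Fleming–Harrington `w = Ŝ⁻(t)^ρ(1−Ŝ⁻(t))^γ` on the pooled
  left-continuous NAB curve, with `Ŝ⁻(t_1) = 1` (so any γ > 0 zeroes the
  first event time);
- modest weights `w_j = 1/max(S̃(t_{j−1}), S̃(t*))` on the pooled KM curve
  with `S̃(t_0) = 1`: weights start at 1, are non-decreasing, and freeze at
  `1/S̃(t*)` after `t*`. Defaults for `t*` are 6 or 8 months — large enough
  to cover plausible onset delays without tuning to a specific scenario.

MaxCombo takes `z_max = max_a z_a` over a set of weightings (default FH
(0,0), (1,0), (1,1), (0,1)) and computes
`p = 1 − P(Z_1 < z_max, …, Z_k < z_max)` under the k-variate normal with
correlation estimated from `Σ w_a w_b v`. Components are the one-sided z
statistics, consistent with the one-sided 2.5% framework used everywhere.
The correlation matrix is symmetrized and, if a rounding-level negative
eigenvalue appears, clipped and rescaled to unit diagonal. The normal
orthant probability is evaluated by scipy's quasi-Monte-Carlo integrator
with a frozen internal seed and a 10,000-point budget: p-values are
bit-reproducible across calls with error around 1e-6, and are clipped into
the exact Bonferroni envelope `[min_a p_a, k·min_a p_a]` that the true
value always satisfies, so quadrature error cannot leak outside it.

## Estimands

All are treatment minus control (or treatment over control), with Wald 95%
intervals and a one-sided p for the benefit direction.

- **RMST** `μ̂_i = Σ_{j=0}^{D'} Ŝ_i(t_j)Δt_j` (step area on `[0, L]`),
  `var(μ̂_i) = Σ_u (Σ_{j≥u} Ŝ_i(t_j)Δt_j)² dN_i(t_u)/Y_i²(t_u)`. `L` is
  always user-specified (6/12/24-month defaults in the study designs);
  a data-dependent `L` is out of scope. `L` beyond an arm's follow-up is an
  error rather than an extrapolation.
- **Milestone survival** `Ŝ_i(t)` with variance
  `Ŝ_i(t)² Σ_{s≤t} dN_i/Y_i²`, on the untransformed scale (matching plain
  normal-approximation Wald tests); log or cloglog transforms would be easy
  to add but are not the default.
- **Median** `τ̂_i = inf{t: Ŝ_i(t) ≤ ½}` with variance
  `λ̂(τ̂)⁻² Σ_{s≤τ̂} dN_i/Y_i²`. The hazard at the median is estimated by a
  Gaussian kernel over the Nelson–Aalen increments,
  `λ̂(t) = Σ_j K_h(t−t_j) dN_j/Y_j`, with a Silverman-rule bandwidth over
  the arm's event times; kernel and bandwidth are configurable because no
  canonical choice exists, so the median's standard error — unlike the
  point estimate — is method-dependent. An arm whose curve never reaches ½
  raises an explicit undefined-median error; the harness reports the rate
  of such replicates instead of silently dropping them.
- **Average hazard ratio** on `[0, L]`:
  `log θ̂ = log Σ Ŵ dΛ̂₁ − log Σ Ŵ dΛ̂₀` with `Ŵ = Ŝ₀⁻Ŝ₁⁻`
  (left-continuous per-arm NAB curves, making the weight predictable) and
  `dΛ̂_i = dN_i/Y_i`; per-arm variance
  `ν̂_i = (Σ Ŵ dΛ̂_i)⁻² Σ Ŵ² dN_i/Y_i²`, `var(log θ̂) = ν̂₀+ν̂₁`. The
  leading factor is the delta-method `(1/x)²` for `log x`. With this
  weight, θ equals the concordance odds `P(T₁>T₀)/P(T₁<T₀)` on `[0, L]`
  and its limit does not depend on the censoring distribution (verified by
  simulation in the test suite).
- **Parametric comparators**: `log T = μ + θx + σW` with W standard normal
  (lognormal) or standard minimum extreme value (Weibull), fitted by
  maximum likelihood with right censoring via lifelines; inference is
  model-based (inverse Hessian) on `(μ, θ, log σ)`. Benefit is θ > 0
  (acceleration factor `exp(θ) > 1`), and the one-sided test rejects for
  large positive `θ̂/se`. The Weibull AFT with a treatment-only covariate
  is simultaneously a proportional-hazards model with HR `exp(−θ/σ)`,
  which the tests check against the Cox fit (statsmodels, Breslow ties).
  Per-arm Weibull fits give the plug-in median `scale·(log 2)^{1/shape}`
  with a delta-method variance from the log-parameter covariance; this
  estimator is known to be biased when the true distribution is not
  Weibull (e.g. crossing hazards) — that fragility is part of what the
  simulation harness is meant to expose.

## Generative models and trial design

Latent event times per arm come from one of:

- **piecewise-exponential** hazards, sampled by exact inversion of the
  piecewise-linear cumulative hazard at `−log U`;
- a **biomarker mixture**: Bernoulli(prevalence) stratum membership, then a
  piecewise-exponential draw per stratum; the marginal survival is the
  prevalence-weighted mixture and the marginal hazard is time-varying even
  though each stratum is proportional;
- an **illness-death model** with constant intensities `a` (pre-progression
  to progression), `b` (pre-progression to death) and `c` (post-progression
  to death): exit from the initial state is Exp(a+b), a progression with
  probability `a/(a+b)`, followed by an Exp(c) residual death time. The
  overall survival `S(t) = e^{−(a+b)t} + a/(a+b−c)(e^{−ct} − e^{−(a+b)t})`
  (with the `a+b = c` limit handled) is used for truths and calibration.

Design defaults mirror a 500-patient trial: 1:1 allocation by random
permutation, i.i.d. uniform recruitment over 18 months (equivalent in
distribution to a constant-rate Poisson process conditioned on n, and
simpler for a fixed sample size), a cutoff at the calendar time of the
375th event with administrative censoring of ongoing follow-up, and 10%
random drop-out. The drop-out rate λ_c solves

    p = ½·Λc/(Λc+Λ₀) + ½·Λc/(Λc+Λ₁),   Λc = λ_c·t_max,

where Λ_i are the arms' cumulative event hazards at the horizon `t_max`,
defined as the larger of the two arms' times at which survival reaches
1/10,000. For exponential arms this is exact
(`λ_c = λp/(1−p)` when the arms share rate λ); for non-constant hazards it
is the cumulative-hazard-ratio approximation built into the design.
Random censoring acts on the patient time scale, independent of arm. If
the event target is unreachable the simulator returns full follow-up with
a warning rather than failing, and downstream code treats the dataset like
any other.

Within the progression family the null (equal-arms) setting uses the
control model with a post/pre-progression hazard multiplier of 2 — an
increasing hazard after progression; the implementation accepts any
positive multiplier, including values below 1.

## Effect calibration

`schoenfeld_target` converts (control median 12 months, d = 375 events,
one-sided α = 2.5%, power 80%) into the proportional-hazards reference
effect `|log hr*| = 2(z_{1−α}+z_{1−β})/√d` (1:1 allocation), i.e.
hr* ≈ 0.7488, a treatment median of `12/hr* ≈ 16.03` months and a target
median difference of ≈ 4.03 months = 123 days. Each family's free
parameter is then root-solved (bracketed Brent on `(10⁻⁶, 10)`, tolerance
1e-12) so the treatment arm's overall-survival median equals the target:

- delayed onset: `λ₀·delay + HR·λ₀·(m₁−delay) = log 2`, giving the
  canonical sequence 0.75/0.71/0.67/0.60/0.50 for delays 0–8 months;
- crossing hazards: `hr_pre·Λ₀(cross) + HR·(Λ₀(m₁)−Λ₀(cross)) = log 2`
  (0.75/0.64/0.50/0.30 at hr_pre 1.5; 0.43 at hr_pre 3, crossing 2);
- subgroups: the biomarker-negative HR solves the prevalence-weighted
  mixture survival at `m₁` equal to ½, with `HR_pos = ratio·HR_neg`;
- progression: one HR scales the treatment arm's total pre-progression
  exit intensity, the progression/death split honors the treatment
  progression proportion, the post-progression intensity is shared with
  control, and the HR is solved on the analytic three-state survival.

Printed two-decimal ratios are roundings of the solver output. Every
calibrated scenario's true median difference agrees with the target to
1e-6 months when recomputed independently by `true_summaries` (quadrature
with absolute tolerance ~1e-10, closed forms where available).

## Replication harness

Per replication the harness simulates a trial, builds the counting process
once, and applies every requested method at one-sided α = 2.5%. Per-rep
generators are spawned as `SeedSequence(master, spawn_key=(rep,))`, so
results are bit-reproducible and extending the method list never changes
earlier replications' data. Rejection rates carry binomial standard errors
`√(r(1−r)/n)`; coverage and bias are measured against `true_summaries`
values and exclude replicates with undefined estimands, whose rate is
reported separately (how such replicates should enter the denominators is
genuinely ambiguous; reporting them separately keeps both readings
recoverable).

Grading condenses method comparisons: for power, `*`/`+`/`~`/`−` bands at
4 and 8 simulation standard errors against the log-rank test or the
per-scenario best method (ties share `*`); for coverage, ±2.3 SSE around
95% (≈ the 99% normal quantile, about one percentage point at 2,500
replications); for bias, ±0.05 on the AHR scale and ±5% of the control-arm
parameter for difference estimands, with the conservative direction graded
`~` and the anti-conservative direction `−` (benefit is positive for
differences, below 1 for the AHR, so the harmful sign differs by scale).

## Problem sizes and what the tests show

The test suite and acceptance script run at desk scale: the null-design
type-I error uses 2,500 replications in the tests and 5,000 in the
acceptance script (3-σ Monte-Carlo bands of ±0.9 and ±0.7 percentage
points around 2.5%), power patterns use 400–500 replications per scenario,
and coverage checks 400 replications at n = 2,000. At these sizes the
qualitative orderings (late weights gain under delayed onset, early
weights collapse under crossing hazards, MaxCombo tracks the best test)
are stable; full-battery grading across thousands of scenarios at 2,500
replications each is supported by the same harness but is an overnight
job, not part of the default suite.

The simulator emulates the structural features that drive NPH method
behavior — effect timing, mixtures, progression, event-driven follow-up,
independent drop-out. It does not emulate informative censoring, treatment
switching, covariate-dependent hazards, or non-canonical recruitment
patterns; conclusions from passing tests are therefore about the methods'
operating characteristics under independent censoring and the stated
generative families, not about robustness beyond them.

## Known limitations

- The median's standard error depends on the kernel bandwidth choice; only
  coverage behavior, not a specific SE value, should be compared across
  implementations.
- The milestone estimator is unstable when few subjects remain at risk at
  the milestone; the harness surfaces this as undefined-estimate rates and
  (at 24 months with heavy censoring) visible bias.
- The MVN orthant probability is accurate to ~1e-6, ample for testing at
  2.5% but not for extreme tail p-values.
- Stratified tests, left truncation, interval censoring and group-sequential
  monitoring are out of scope.
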